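"""Diagnostic curve tables: homoplasy vs k, sampling ratios vs coverage.

Pure functions of the analytic models; the tables users plot to pick k and
decide whether to filter singletons.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .homoplasy import HomoplasyParams, p_h_random
from .sampling import (
    SamplingParams,
    distance_bias,
    distance_variance,
    observed_true_ratios,
    tip_correction,
)

__all__ = ["homoplasy_curves", "sampling_curves"]


def homoplasy_curves(
    g_list: Sequence[float],
    u_list: Sequence[float],
    d_list: Sequence[float],
    k_range: Sequence[int],
) -> pd.DataFrame:
    """p_h as a function of k for every (g, u, d) combination, long format,
    with the no-homoplasy baseline e^{-kd} alongside."""
    rows = []
    for g in g_list:
        for u in u_list:
            for d in d_list:
                for k in k_range:
                    pred = p_h_random(HomoplasyParams(g=g, u=u, k=k, d=d))
                    rows.append(
                        dict(g=g, u=u, d=d, k=k, p_h=pred.p_h, baseline=pred.baseline)
                    )
    return pd.DataFrame(rows)


def sampling_curves(
    c_grid: Sequence[float],
    r: float,
    E: float,
    k_list: Sequence[int],
    d: float = 0.1,
    n_s: float = 1e5,
) -> pd.DataFrame:
    """p_t, p_s, bias, variance and tip correction over a coverage grid, for
    filtered and unfiltered counting."""
    rows = []
    for k in k_list:
        for filtered in (False, True):
            for c in c_grid:
                sp = SamplingParams(c=c, r=r, E=E, k=k, filtered=filtered)
                rates = observed_true_ratios(sp, d)
                row = dict(
                    k=k,
                    filtered=filtered,
                    c=c,
                    p_r=rates.p_r,
                    p_e=rates.p_e,
                    p_ta=rates.p_ta,
                    p_sa=rates.p_sa,
                    p_t=rates.p_t,
                    p_s=rates.p_s,
                )
                try:
                    row["bias"] = distance_bias(rates, k)
                    row["variance"] = distance_variance(rates, n_s, k)
                    row["D_tip"] = tip_correction(sp)
                except ValueError:
                    row["bias"] = row["variance"] = row["D_tip"] = np.nan
                rows.append(row)
    return pd.DataFrame(rows)
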