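"""Sampling model: incomplete coverage, sequencing error, singleton filtering.

A k-mer locus is recovered only if some read covers it entirely and without a
sequencing error inside the window.  With coverage c and read length r, the
number of reads whose error-free start would cover a given locus is
approximately Poisson with mean L = c (r - k + 1) / r; with per-base error
rate E, the error-free coverings are Poisson with mean lambda = L (1 - E)^k.
Everything in this module follows from those two rates:

  coverage retention   p_r  = 1 - e^{-L}           (unfiltered)
                       p_rf = 1 - (1 + L) e^{-L}   (singletons filtered)
  error retention      p_e  = P(Pois(lam) >= 1) / P(Pois(L) >= 1)
                       p_ef = P(Pois(lam) >= 2) / P(Pois(L) >= 2)
  false k-mer rates    p_ta = L (1 - (1 - E)^k)       per true total k-mer
                       p_sa = L (1 - (1 - E/3)^{kd})  per true shared k-mer
                       (both ~0 when singletons are filtered)

which combine into the observed/true ratios p_t = p_r p_e + p_ta and
p_s = p_r^2 p_e^2 + p_sa (filtered variants substitute p_rf, p_ef and drop the
false rates), the additive distance bias D* - D = -(1/k) log(p_s/p_t), its
approximate variance, and the analytic tip correction

  D_tip = (1/2k) log((p_r p_e + p_ta) / (p_r^2 p_e^2)),

which is independent of the true distance between species and is subtracted
from terminal branches after the topology has been fitted.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "SamplingParams",
    "SamplingRates",
    "coverage_retention",
    "error_retention",
    "false_kmer_rates",
    "observed_true_ratios",
    "distance_bias",
    "distance_variance",
    "tip_correction",
    "average_tip_correction",
]


@dataclass(frozen=True)
class SamplingParams:
    """Per-taxon sequencing characteristics.

    c : fold coverage (mean read bases per genome base).
    r : read length in bp (mean if heterogeneous); must exceed k.
    E : per-base sequencing error rate.
    k : k-mer length.
    filtered : singleton k-mers removed.
    """

    c: float
    r: float
    E: float
    k: int
    filtered: bool = False

    def __post_init__(self) -> None:
        if self.r <= self.k:
            raise ValueError(f"read length {self.r} must exceed k={self.k}")
        if not 0 <= self.E < 1:
            raise ValueError("error rate must be in [0, 1)")
        if self.c < 0:
            raise ValueError("coverage must be >= 0")

    @property
    def L(self) -> float:
        """Expected k-mer-spanning read starts per locus: c (r - k + 1)/r."""
        return self.c * (self.r - self.k + 1) / self.r

    @property
    def lam(self) -> float:
        """Error-free covering rate: L (1 - E)^k."""
        return self.L * (1.0 - self.E) ** self.k


@dataclass(frozen=True)
class SamplingRates:
    """Retention probabilities and observed/true ratios for one parameter set.

    q_t and q_s are the *true*-k-mer joint retention probabilities; p_t and
    p_s additionally include false k-mers and may exceed 1.
    """

    p_r: float
    p_e: float
    p_ta: float
    p_sa: float

    @property
    def q_t(self) -> float:
        return self.p_r * self.p_e

    @property
    def q_s(self) -> float:
        return (self.p_r * self.p_e) ** 2

    @property
    def p_t(self) -> float:
        return self.q_t + self.p_ta

    @property
    def p_s(self) -> float:
        return self.q_s + self.p_sa


def coverage_retention(params: SamplingParams) -> float:
    """Probability a k-mer locus is covered (>=1 or >=2 times if filtered)."""
    L = params.L
    if params.filtered:
        return -math.expm1(-L) - L * math.exp(-L)  # 1 - (1+L) e^{-L}
    return -math.expm1(-L)


def error_retention(params: SamplingParams) -> float:
    """Probability a covered k-mer survives sequencing error.

    Conditional form P(Pois(lambda) >= m) / P(Pois(L) >= m) with m = 1
    (unfiltered) or m = 2 (filtered); both reduce to ratios of
    difference-of-exponentials expressions.
    """
    L, lam = params.L, params.lam
    if L == 0.0:
        return (1.0 - params.E) ** params.k  # limit as coverage -> 0
    if params.filtered:
        num = -math.expm1(-lam) - lam * math.exp(-lam)
        den = -math.expm1(-L) - L * math.exp(-L)
    else:
        num = -math.expm1(-lam)
        den = -math.expm1(-L)
    if den == 0.0:
        return 0.0
    return num / den


def false_kmer_rates(params: SamplingParams, d: float = 0.0) -> tuple[float, float]:
    """(p_ta, p_sa): false total and false shared k-mers per true k-mer.

    d is a provisional distance for the false-shared rate (errors mimicking
    homoplasy between diverged genomes).  Filtering makes both negligible.
    """
    if d < 0:
        raise ValueError("distance must be >= 0")
    if params.filtered:
        return 0.0, 0.0
    L, E, k = params.L, params.E, params.k
    p_ta = L * (1.0 - (1.0 - E) ** k)
    p_sa = L * (1.0 - (1.0 - E / 3.0) ** (k * d))
    return p_ta, p_sa


def observed_true_ratios(params: SamplingParams, d: float = 0.0) -> SamplingRates:
    """Compose retention and false rates into observed/true k-mer ratios."""
    p_r = coverage_retention(params)
    p_e = error_retention(params)
    p_ta, p_sa = false_kmer_rates(params, d)
    return SamplingRates(p_r=p_r, p_e=p_e, p_ta=p_ta, p_sa=p_sa)


def distance_bias(rates: SamplingRates, k: int) -> float:
    """Additive bias of the observed-data distance: D* - D = -(1/k) log(p_s/p_t)."""
    if rates.p_s <= 0 or rates.p_t <= 0:
        raise ValueError("p_s and p_t must be positive")
    return -math.log(rates.p_s / rates.p_t) / k


def distance_variance(
    rates: SamplingRates,
    n_s: float,
    k: int,
    nt_variant: float | None = None,
) -> float:
    """Approximate sampling variance of D* (on the D scale, i.e. /k^2).

    Both log terms carry a 1/n_s factor by default; pass ``nt_variant=n_t``
    to use 1/n_t in the total-k-mer term instead (the symmetric reading).
    """
    if n_s <= 0:
        raise ValueError("n_s must be positive")
    q_s, q_t = rates.q_s, rates.q_t
    n2 = nt_variant if nt_variant is not None else n_s
    t1 = math.log1p((q_s * (1 - q_s) + rates.p_sa) / (n_s * (q_s + rates.p_sa) ** 2))
    t2 = math.log1p((q_t * (1 - q_t) + rates.p_ta) / (n2 * (q_t + rates.p_ta) ** 2))
    return (t1 + t2) / k**2


def tip_correction(params: SamplingParams) -> float:
    """Analytic terminal-branch shortening D_tip = (D* - D)/2.

    Excludes the false-shared rate by construction, so it does not depend on
    the true distance between species.
    """
    p_r = coverage_retention(params)
    p_e = error_retention(params)
    p_ta, _ = false_kmer_rates(params, 0.0)
    q_t = p_r * p_e
    if q_t <= 0:
        raise ValueError("no k-mer retention at these parameters")
    return math.log((q_t + p_ta) / q_t**2) / (2.0 * params.k)


def average_tip_correction(
    per_taxon: Sequence[SamplingParams],
    n_t_per_taxon: Sequence[float],
    taxa: Sequence[str] | None = None,
) -> dict[str, float] | np.ndarray:
    """Averaged tip correction for heterogeneous taxa.

    For each pair the correction is computed from the parameters of the taxon
    with the lower n_t, and every tip is trimmed by the mean over all pairs.
    Returns a per-taxon mapping (or array if no names given); all values are
    equal by construction.
    """
    n = len(per_taxon)
    if n < 2:
        raise ValueError("need at least 2 taxa")
    if len(n_t_per_taxon) != n:
        raise ValueError("n_t list must match params list")
    vals = []
    for i in range(n):
        for j in range(i + 1, n):
            low = i if n_t_per_taxon[i] <= n_t_per_taxon[j] else j
            vals.append(tip_correction(per_taxon[low]))
    mean = float(np.mean(vals))
    if taxa is None:
        return np.full(n, mean)
    if len(taxa) != n:
        raise ValueError("taxa list must match params list")
    return {t: mean for t in taxa}


def variance_crossover_coverage(
    r: float,
    E: float,
    k: int,
    n_s: float,
    d: float = 0.1,
    c_grid: np.ndarray | None = None,
) -> float:
    """Coverage at which filtering starts to reduce the distance variance.

    Scans a coverage grid and returns the first c where the filtered variance
    drops below the unfiltered one (the filter-or-not decision point).
    """
    if c_grid is None:
        c_grid = np.arange(0.5, 20.01, 0.05)
    for c in c_grid:
        vu = distance_variance(
            observed_true_ratios(SamplingParams(c, r, E, k, False), d), n_s, k
        )
        vf = distance_variance(
            observed_true_ratios(SamplingParams(c, r, E, k, True), d), n_s, k
        )
        if vf < vu:
            return float(c)
    warnings.warn("no crossover found on the coverage grid")
    return math.inf
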