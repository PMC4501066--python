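"""K-mer homoplasy: how much of the observed k-mer sharing is not homologous.

Identical k-mers can occur at non-homologous locations (repeats, chance) or be
re-created by mutation, inflating n_s/n_t above the no-homoplasy expectation
e^{-kd}.  Three routes contribute:

  p1 - at least one of the multiple copies of a k-mer escapes mutation;
  p2 - a mutation elsewhere re-creates the k-mer;
  p3 - all copies mutate but their products already exist in the other genome;

combined as  p_h = p1 + (1-p1) p2 + (1-p1)(1-p2) p3.

p1 and p3 need the copy-number spectrum Q_k of the shorter genome.  With an
empirical spectrum q (q[j] = fraction of distinct k-mers with j total copies):

  1 - p1 = sum_{j>=1} (1 - e^{-kd})^j q[j]
  p2     = (1 - e^{-kd}) (1 - (1-P)^g)
  p3     = 0.5 e^{-kd} sum_{j>=1} (1 - (1-P)^g)^j q[j]

where P = 2 (0.5 - u + u^2)^k is the probability that two random k-mer loci in
a genome of GC content u carry the identical canonical k-mer, and g is the
genome length.  For a random (i.i.d.) genome Q_k is Binomial(g, P) conditioned
on presence, which gives the closed forms

  p1 = 1 - ((1 - P e^{-kd})^g - (1-P)^g) / (1 - (1-P)^g)
  p3 = 0.5 e^{-kd} ((1 - P (1-P)^g)^g - (1-P)^g) / (1 - (1-P)^g)

evaluated in log space so g up to 1e10 is stable.  The exponent in the p1/p3
sums is the *total* copy number j >= 1: this is the only indexing under which
the binomial substitution reproduces the closed forms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .kmers import KmerSpectrum

__all__ = [
    "HomoplasyParams",
    "HomoplasyPrediction",
    "match_probability",
    "canonical_kmer_space",
    "p_h_random",
    "p_h_empirical",
    "select_k",
]

SELECT_K_TOL = 0.05  # relative excess p_h/e^{-kd} - 1 regarded as negligible


@dataclass(frozen=True)
class HomoplasyParams:
    """Inputs of the homoplasy model.

    g : genome length in bp (the shorter genome of the pair).
    u : GC content in (0, 1).
    k : k-mer length.
    d : true (or assumed) distance in substitutions per site.
    """

    g: float
    u: float = 0.5
    k: int = 21
    d: float = 0.1

    def __post_init__(self) -> None:
        if not 0 < self.u < 1:
            raise ValueError("GC content must be in (0, 1)")
        if self.g < 1:
            raise ValueError("genome length must be >= 1")
        if self.d < 0:
            raise ValueError("distance must be >= 0")

    @property
    def P(self) -> float:
        return match_probability(self.u, self.k)


@dataclass(frozen=True)
class HomoplasyPrediction:
    """Component probabilities and the combined sharing probability."""

    p1: float
    p2: float
    p3: float
    baseline: float  # e^{-kd}, the no-homoplasy expectation

    @property
    def p_h(self) -> float:
        return self.p1 + (1 - self.p1) * self.p2 + (1 - self.p1) * (1 - self.p2) * self.p3


def match_probability(u: float, k: int) -> float:
    """P = 2 (0.5 - u + u^2)^k: chance that two random k-mer loci carry the
    identical canonical k-mer; minimised at u = 0.5 where it is 2*4^-k."""
    if not 0 < u < 1:
        raise ValueError("GC content must be in (0, 1)")
    return 2.0 * (0.5 - u + u * u) ** k


def canonical_kmer_space(k: int) -> int:
    """Exact number of distinct canonical k-mers: 4^k/2 for odd k; for even k
    the 4^{k/2} reverse-complement palindromes are their own canonical form,
    giving (4^k + 4^{k/2}) / 2."""
    if k % 2:
        return 4**k // 2
    return (4**k + 4 ** (k // 2)) // 2


def _pow1m(x: float, g: float) -> float:
    """(1 - x)^g via exp(g * log1p(-x)), stable for tiny x and huge g."""
    if x >= 1.0:
        return 0.0
    return math.exp(g * math.log1p(-x))


def p_h_random(params: HomoplasyParams) -> HomoplasyPrediction:
    """Sharing probability for a random i.i.d. ancestral genome (closed form)."""
    g, k, d, P = params.g, params.k, params.d, params.P
    base = math.exp(-k * d)
    q0 = _pow1m(P, g)  # (1-P)^g : chance a given k-mer is absent
    denom = 1.0 - q0
    if denom <= 0.0:
        # degenerate: no k-mer present; no sharing possible
        return HomoplasyPrediction(0.0, 0.0, 0.0, base)
    p1 = 1.0 - (_pow1m(P * base, g) - q0) / denom
    p2 = (1.0 - base) * denom
    p3 = 0.5 * base * (_pow1m(P * q0, g) - q0) / denom
    return HomoplasyPrediction(p1, p2, p3, base)


def p_h_empirical(spec: KmerSpectrum, params: HomoplasyParams) -> HomoplasyPrediction:
    """Sharing probability from an empirical copy-number spectrum of the
    shorter genome (unfiltered counts)."""
    if spec.k != params.k:
        raise ValueError(f"spectrum k={spec.k} does not match params k={params.k}")
    g, k, d, P = params.g, params.k, params.d, params.P
    base = math.exp(-k * d)
    j = np.arange(spec.q.size)
    x1 = 1.0 - base
    p1 = 1.0 - float(np.sum(x1**j * spec.q))
    present = 1.0 - _pow1m(P, g)
    p2 = (1.0 - base) * present
    p3 = 0.5 * base * float(np.sum(present**j * spec.q))
    return HomoplasyPrediction(p1, p2, p3, base)


def homoplasy_excess(params: HomoplasyParams, spec: KmerSpectrum | None = None) -> float:
    """Relative excess p_h / e^{-kd} - 1 (0 means no homoplasy)."""
    pred = p_h_empirical(spec, params) if spec is not None else p_h_random(params)
    return pred.p_h / pred.baseline - 1.0


def select_k(
    g: float,
    d_max: float = 0.1,
    u: float = 0.5,
    tol: float = SELECT_K_TOL,
    spec_by_k: dict[int, KmerSpectrum] | None = None,
    k_min: int = 5,
    k_max: int = 31,
) -> int:
    """Smallest k whose homoplasy excess is below `tol` for all d <= d_max.

    The excess grows with d, so d_max is the binding case and is the value
    checked.  With an empirical spectrum per k (``spec_by_k``), the excess is
    evaluated from that genome's actual complexity instead of the random-
    genome closed form.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    for k in range(k_min, k_max + 1):
        params = HomoplasyParams(g=g, u=u, k=k, d=d_max)
        spec = spec_by_k.get(k) if spec_by_k else None
        if spec is not None and spec.k != k:
            continue
        if homoplasy_excess(params, spec) < tol:
            return k
    raise ValueError(
        f"no k <= {k_max} reduces homoplasy excess below {tol} for g={g:g}, "
        f"u={u}, d={d_max}; inspect the p_h curve and consider a larger k"
    )
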