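"""Two-stage bootstraps for k-mer phylogenies.

Stage 1 quantifies sampling variation (incomplete coverage, sequencing
error), stage 2 additionally evolutionary variation (the mutation process
itself).  Two modes:

* nonparametric - resample reads with replacement per taxon (stage 1), then
  additionally resample round(M/k) rows of the merged presence/absence table
  with replacement (stage 2).  Only 1 in k rows is kept because adjacent
  k-mers overlap: each nucleotide is covered by up to k k-mers, so distinct
  rows are not independent observations (a block-bootstrap argument).

* parametric - perturb the distance matrix directly.  Stage 1 adds
  independent zero-mean Gaussian noise whose variance is the sampling
  variance of log(n_s*/n_t*) augmented by read-overlap factors
  (1 + (r-k)/L) and (1 + w), w = sum_{i=1}^{k-1} 2i/(k(r-k+1)) max(0, r-2k+i+1),
  scaled to the D scale; the predicted SD is inflated by a factor of 2
  because the approximation can be off by up to ~50%, making the bootstrap
  conservative.  Stage 2 adds correlated Gaussian noise with per-pair
  evolutionary variance

      (1/(k^2 n_t)) [ (e^{kD} - 1) + 2 sum_{i=1}^{k-1} (e^{iD} - 1) ]

  (the k-mer-overlap generalisation of the single-site variance; at k = 1 it
  reduces to (e^D - 1)/n_t) and covariance between taxon pairs proportional
  to the evolutionary history they share: the length of the overlap of their
  two tree paths, times the geometric mean of the pairs' variance per unit
  path length.

Support is reported per internal bipartition as the count of replicates (of
B) whose fitted tree contains it, separately for stage 1 and stage 2.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .distance import DistanceMatrix, build_matrix_from_counts
from .kmers import KmerConfig, KmerTable, count_kmers_codes, flatten_read_matrix
from .sampling import SamplingParams, SamplingRates, distance_variance
from .tree import PhyloTree, fit_tree

__all__ = [
    "BootstrapConfig",
    "SupportTable",
    "resample_reads",
    "merged_presence",
    "resample_rows",
    "nonparametric_bootstrap",
    "parametric_stage1_sd",
    "parametric_stage2_variance",
    "shared_branch_covariance",
    "parametric_bootstrap",
]


@dataclass(frozen=True)
class BootstrapConfig:
    """Replicate count, stage, seed and SD inflation for either mode."""

    B: int = 100
    seed: int = 0
    sd_inflation: float = 2.0

    def __post_init__(self) -> None:
        if self.B < 1 or self.sd_inflation <= 0:
            raise ValueError("need B >= 1 and sd_inflation > 0")


@dataclass
class SupportTable:
    """Per-bipartition replicate counts for stage 1 and stage 2."""

    taxa: list[str]
    B: int
    stage1: dict[int, int] = field(default_factory=dict)
    stage2: dict[int, int] = field(default_factory=dict)

    def describe(self, mask: int) -> str:
        names = [t for i, t in enumerate(self.taxa) if (mask >> i) & 1]
        return "|".join(names)


def resample_reads(reads: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw N reads with replacement from an (N, r) read matrix."""
    n = reads.shape[0]
    if n == 0:
        raise ValueError("no reads to resample")
    idx = rng.integers(0, n, size=n)
    return reads[idx]


def merged_presence(tables: list[KmerTable]) -> tuple[np.ndarray, np.ndarray]:
    """Merged table: (union k-mers, (M, T) boolean presence matrix)."""
    union = np.unique(np.concatenate([t.kmers for t in tables]))
    pres = np.zeros((union.size, len(tables)), dtype=bool)
    for j, t in enumerate(tables):
        pres[np.searchsorted(union, t.kmers), j] = True
    return union, pres


def resample_rows(
    presence: np.ndarray, k: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Block-bootstrap the merged table: round(M/k) rows with replacement.

    Returns (NS, NT) count matrices computed on the reduced table; resampled
    duplicates count with their multiplicity.
    """
    M = presence.shape[0]
    size = max(1, int(round(M / k)))
    idx = rng.integers(0, M, size=size)
    sub = presence[idx]
    ntax = presence.shape[1]
    counts = sub.astype(np.int64)
    NT_diag = counts.sum(axis=0)
    NS = counts.T @ counts  # pairwise co-presence with multiplicity
    NT = np.minimum.outer(NT_diag, NT_diag)
    np.fill_diagonal(NT, NT_diag)
    np.fill_diagonal(NS, NT_diag)
    return NS, NT


def _record(support: dict[int, int], tree: PhyloTree) -> None:
    for m in tree.bipartitions(internal_only=True):
        support[m] = support.get(m, 0) + 1


def nonparametric_bootstrap(
    reads_by_taxon: dict[str, np.ndarray],
    kcfg: KmerConfig,
    cfg: BootstrapConfig,
) -> tuple[SupportTable, PhyloTree]:
    """Read-resampling (stage 1) + row-resampling (stage 2) bootstrap.

    `reads_by_taxon` maps taxon -> (N, r) uint8 read matrix (assembled-only
    input has no reads to resample; use the parametric mode there).  Returns
    the support table and the reference tree annotated with stage-2 support.
    """
    for t, r in reads_by_taxon.items():
        if r.ndim != 2 or r.shape[0] == 0:
            raise ValueError(
                f"taxon {t!r} has no read matrix; the nonparametric bootstrap "
                "needs reads (use the parametric bootstrap for assemblies)"
            )
    rng = np.random.default_rng(cfg.seed)
    taxa = sorted(reads_by_taxon)

    def tables_from(reads: dict[str, np.ndarray]) -> list[KmerTable]:
        return [
            count_kmers_codes([flatten_read_matrix(reads[t])], kcfg, t) for t in taxa
        ]

    ref_tables = tables_from(reads_by_taxon)
    from .distance import build_distance_matrix

    ref_tree = fit_tree(build_distance_matrix(ref_tables))
    table = SupportTable(taxa=ref_tree.taxa, B=cfg.B)
    for _ in range(cfg.B):
        res = {t: resample_reads(reads_by_taxon[t], rng) for t in taxa}
        tabs = tables_from(res)
        M1 = build_distance_matrix(tabs)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            t1 = fit_tree(M1)
            _record(table.stage1, t1)
            _, pres = merged_presence(tabs)
            NS, NT = resample_rows(pres, kcfg.k, rng)
            M2 = build_matrix_from_counts(taxa, NS, NT, kcfg.k, M1.filtered)
            t2 = fit_tree(M2)
        _record(table.stage2, t2)
    annotated = ref_tree.copy()
    annotated.support = {
        m: table.stage2.get(m, 0)
        for m in annotated.bipartitions(internal_only=True)
    }
    return table, annotated


def stage1_overlap_w(k: int, r: float) -> float:
    """w = sum_{i=1}^{k-1} 2i/(k(r-k+1)) max(0, r-2k+i+1)."""
    i = np.arange(1, k)
    return float(np.sum(2 * i / (k * (r - k + 1)) * np.maximum(0.0, r - 2 * k + i + 1)))


def parametric_stage1_sd(
    params: SamplingParams,
    rates: SamplingRates,
    n_s: float,
    sd_inflation: float = 2.0,
) -> float:
    """Stage-1 (sampling) SD of D* for one pair, inflated to be conservative.

    The sampling variance of log(n_s*/n_t*) with the shared-term unchanged
    and the total-term augmented by the read-overlap factors, then /k^2 and
    sqrt, times the inflation factor.
    """
    k, r, L = params.k, params.r, params.L
    q_s, q_t = rates.q_s, rates.q_t
    w = stage1_overlap_w(k, r)
    t1 = math.log1p((q_s * (1 - q_s) + rates.p_sa) / (n_s * (q_s + rates.p_sa) ** 2))
    overlap = (1 + (r - k) / L) if L > 0 else 1.0
    t2 = math.log1p(
        (q_t * (1 - q_t) * overlap + rates.p_ta * (1 + w))
        / (n_s * (q_t + rates.p_ta) ** 2)
    )
    var = (t1 + t2) / k**2
    return sd_inflation * math.sqrt(max(var, 0.0))


def parametric_stage2_variance(k: int, n_t: float, D: float) -> float:
    """Evolutionary variance of D for one pair, with k-mer overlap covariance:

        (1/(k^2 n_t)) [ (e^{kD} - 1) + 2 sum_{i=1}^{k-1} (e^{iD} - 1) ]

    At k = 1 this is (e^D - 1)/n_t, the WLS variance of the distance model.
    """
    if D < 0:
        raise ValueError("distance must be >= 0")
    if n_t <= 0:
        raise ValueError("n_t must be positive")
    i = np.arange(1, k)
    total = math.expm1(k * D) + 2.0 * float(np.sum(np.expm1(i * D)))
    return total / (k**2 * n_t)


def shared_branch_covariance(
    tree: PhyloTree, M: DistanceMatrix
) -> np.ndarray:
    """Covariance of pairwise distances under shared evolutionary history.

    For taxon pairs p = (A,B), q = (C,D) the covariance is the length of the
    shared portion of their tree paths times the geometric mean of the two
    pairs' stage-2 variance per unit path length; the diagonal is the stage-2
    variance itself.  Projected to the nearest positive semidefinite matrix
    (eigenvalue clipping) if rounding makes it indefinite.
    """
    idx = [tree.taxa.index(t) for t in M.taxa]
    A = tree.design_matrix()
    lengths = tree.lengths
    n = M.n_taxa
    # rows of A follow sorted-taxa pair order; map M's pair order onto it
    tpairs = {(i, j): p for p, (i, j) in enumerate(
        [(i, j) for i in range(n) for j in range(i + 1, n)]
    )}
    mpairs = M.pair_index()
    rows = []
    for (i, j) in mpairs:
        a, b = idx[i], idx[j]
        rows.append(tpairs[(min(a, b), max(a, b))])
    P = A[rows]  # path incidence per M pair
    path_len = P @ lengths
    var = np.array(
        [
            parametric_stage2_variance(M.k, max(M.n_t[i, j], 1), M.D[i, j])
            for i, j in mpairs
        ]
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        per_unit = np.where(path_len > 0, var / path_len, 0.0)
    shared = (P * lengths) @ P.T  # shared path length between pair-paths
    C = shared * np.sqrt(np.outer(per_unit, per_unit))
    np.fill_diagonal(C, var)
    # symmetrise and clip tiny negative eigenvalues
    C = (C + C.T) / 2.0
    evals, evecs = np.linalg.eigh(C)
    if evals.min() < -1e-12 * max(evals.max(), 1e-300):
        warnings.warn("covariance projected to nearest positive semidefinite")
    evals = np.clip(evals, 0.0, None)
    return (evecs * evals) @ evecs.T


def parametric_bootstrap(
    M: DistanceMatrix,
    tree: PhyloTree,
    params_by_taxon: dict[str, SamplingParams],
    cfg: BootstrapConfig,
    rates_by_taxon: dict[str, SamplingRates] | None = None,
    stage: int = 2,
) -> tuple[SupportTable, PhyloTree]:
    """Distance-contamination bootstrap; runtime independent of genome size.

    Stage 1 adds independent Gaussian noise with `parametric_stage1_sd` per
    pair (parameters of the lower-n_t taxon of the pair); stage 2 adds
    correlated Gaussian noise from `shared_branch_covariance`.  Contaminated
    distances are floored at 0 and the tree refit per replicate.
    """
    from .sampling import observed_true_ratios

    rng = np.random.default_rng(cfg.seed)
    n = M.n_taxa
    mpairs = M.pair_index()
    sd1 = np.empty(len(mpairs))
    for p, (i, j) in enumerate(mpairs):
        low = i if M.n_t[i, i] <= M.n_t[j, j] else j
        sp = params_by_taxon[M.taxa[low]]
        rates = (
            rates_by_taxon[M.taxa[low]]
            if rates_by_taxon is not None
            else observed_true_ratios(sp, M.D[i, j])
        )
        sd1[p] = parametric_stage1_sd(
            sp, rates, max(M.n_s[i, j], 1), cfg.sd_inflation
        )
    cov2 = shared_branch_covariance(tree, M) if stage >= 2 else None
    if cov2 is not None:
        ev, U = np.linalg.eigh(cov2)
        half = U * np.sqrt(np.clip(ev, 0.0, None))
    d0 = M.condensed()
    table = SupportTable(taxa=sorted(M.taxa), B=cfg.B)
    ref = tree
    for _ in range(cfg.B):
        e1 = rng.normal(0.0, sd1)
        d1 = np.maximum(d0 + e1, 0.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _record(table.stage1, fit_tree(_matrix_with(M, d1)))
            if stage >= 2:
                e2 = half @ rng.standard_normal(half.shape[1])
                d2 = np.maximum(d1 + e2, 0.0)
                _record(table.stage2, fit_tree(_matrix_with(M, d2)))
    annotated = ref.copy()
    src = table.stage2 if stage >= 2 else table.stage1
    annotated.support = {
        m: src.get(m, 0) for m in annotated.bipartitions(internal_only=True)
    }
    return table, annotated


def _matrix_with(M: DistanceMatrix, condensed: np.ndarray) -> DistanceMatrix:
    D = np.zeros_like(M.D)
    for p, (i, j) in enumerate(M.pair_index()):
        D[i, j] = D[j, i] = condensed[p]
    return DistanceMatrix(M.taxa, D, M.n_s, M.n_t, M.k, M.filtered)
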