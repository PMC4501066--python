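"""Simulators for validating the pipeline without external data.

Two generators mirror the validation experiments the method was designed
around:

* sequence evolution along a tree under an HKY substitution process
  (transition bias kappa = 2) with indels at 10% of the substitution rate,
  lengths uniform on 1..5, insertions and deletions equally likely;
* uniform short-read sampling with i.i.d. per-base errors (default 70 bp
  reads, 1% error), the read model behind all coverage/error corrections.

Branch lengths are expected substitutions per site (Poisson), the same scale
as the distance estimator.  Genomes are linear; reads start uniformly in
[0, g - r], so coverage dips within r of the ends.  A ``circular`` flag wraps
read placement instead, which matches the sampling model's stationarity
assumption exactly and is what the Monte-Carlo oracles use.
"""

from __future__ import annotations

import numpy as np

import dendropy

from .kmers import codes_to_seq

__all__ = [
    "EvolutionParams",
    "ReadSimParams",
    "random_genome",
    "evolve_sequence",
    "evolve_on_tree",
    "pair_at_distance",
    "simulate_reads",
    "benchmark_tree_12",
    "BENCHMARK_TREE_12",
    "write_fasta",
    "write_fastq",
]

from dataclasses import dataclass


@dataclass(frozen=True)
class EvolutionParams:
    """HKY + indel model parameters.

    kappa : transition/transversion rate ratio (HKY convention).
    indel_fraction : combined insertion+deletion rate as a fraction of the
        substitution rate.
    indel_max_len : indel lengths are uniform integers on [1, indel_max_len].
    gc : equilibrium GC content (base frequencies (1-u)/2, u/2, u/2, (1-u)/2).
    """

    kappa: float = 2.0
    indel_fraction: float = 0.1
    indel_max_len: int = 5
    gc: float = 0.5

    def __post_init__(self) -> None:
        if self.kappa <= 0 or self.indel_fraction < 0:
            raise ValueError("kappa must be > 0 and indel_fraction >= 0")

    @property
    def base_freqs(self) -> np.ndarray:
        u = self.gc
        return np.array([(1 - u) / 2, u / 2, u / 2, (1 - u) / 2])

    def conditional_matrix(self) -> np.ndarray:
        """P(new base | substitution event at old base), rows = old base.

        HKY rates q_xy are kappa*pi_y for transitions (A<->G, C<->T) and pi_y
        for transversions; rows are normalised to sum to 1.
        """
        pi = self.base_freqs
        ts_partner = {0: 2, 1: 3, 2: 0, 3: 1}
        M = np.zeros((4, 4))
        for x in range(4):
            for y in range(4):
                if y == x:
                    continue
                M[x, y] = pi[y] * (self.kappa if y == ts_partner[x] else 1.0)
            M[x] /= M[x].sum()
        return M


@dataclass(frozen=True)
class ReadSimParams:
    """Short-read simulation parameters (r = read length, E = error rate,
    c = fold coverage); mates are treated as independent reads."""

    c: float
    r: int = 70
    E: float = 0.01
    circular: bool = False

    def __post_init__(self) -> None:
        if self.r < 1 or not 0 <= self.E < 1 or self.c < 0:
            raise ValueError("invalid read simulation parameters")


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def random_genome(g: int, u: float = 0.5, seed=None) -> np.ndarray:
    """I.i.d. genome of length g with GC content u, as uint8 codes."""
    if g < 1:
        raise ValueError("genome length must be >= 1")
    rng = _as_rng(seed)
    p = np.array([(1 - u) / 2, u / 2, u / 2, (1 - u) / 2])
    return rng.choice(4, size=g, p=p).astype(np.uint8)


def _substitute(seq: np.ndarray, d: float, M: np.ndarray, rng) -> np.ndarray:
    """Apply Poisson(d) substitutions per site via the conditional matrix."""
    out = seq.copy()
    hits = rng.poisson(d, size=seq.size)
    cum = np.cumsum(M, axis=1)
    # single-hit sites vectorised; multi-hit sites (rare) iterated
    one = np.flatnonzero(hits == 1)
    if one.size:
        u = rng.random(one.size)
        out[one] = (cum[out[one]] < u[:, None]).sum(axis=1)
    for i in np.flatnonzero(hits >= 2):
        for _ in range(hits[i]):
            out[i] = np.searchsorted(cum[out[i]], rng.random(), side="right")
    return out


def _indels(seq: np.ndarray, d: float, params: EvolutionParams, rng) -> np.ndarray:
    """Insertions and deletions at combined rate indel_fraction * d per site."""
    if params.indel_fraction == 0 or d == 0:
        return seq
    g = seq.size
    rate = 0.5 * params.indel_fraction * d  # per site, each channel
    n_del = rng.poisson(rate * g)
    n_ins = rng.poisson(rate * g)
    if n_del:
        starts = rng.integers(0, g, size=n_del)
        lens = rng.integers(1, params.indel_max_len + 1, size=n_del)
        keep = np.ones(g, dtype=bool)
        for s, l in zip(starts, lens):
            keep[s : s + l] = False
        seq = seq[keep]
    if n_ins and seq.size:
        pos = rng.integers(0, seq.size + 1, size=n_ins)
        lens = rng.integers(1, params.indel_max_len + 1, size=n_ins)
        bases = rng.choice(4, size=int(lens.sum()), p=params.base_freqs).astype(np.uint8)
        seq = np.insert(seq, np.repeat(pos, lens), bases)
    return seq


def evolve_sequence(
    seq: np.ndarray, d: float, params: EvolutionParams | None = None, seed=None
) -> np.ndarray:
    """Evolve one branch of length d (expected substitutions per site)."""
    if d < 0:
        raise ValueError("branch length must be >= 0")
    params = params or EvolutionParams()
    rng = _as_rng(seed)
    if d == 0:
        return seq.copy()
    out = _substitute(seq, d, params.conditional_matrix(), rng)
    out = _indels(out, d, params, rng)
    if out.size == 0:
        raise ValueError("sequence vanished through deletions; branch too long")
    return out


def evolve_on_tree(
    ancestor: np.ndarray,
    tree: "dendropy.Tree | str",
    params: EvolutionParams | None = None,
    seed=None,
) -> dict[str, np.ndarray]:
    """Evolve an ancestral sequence down every branch of a (Newick) tree.

    Returns {taxon label: uint8 code array}.  Edge lengths of None are
    treated as 0 (e.g. the root edge of a rooted Newick).
    """
    params = params or EvolutionParams()
    rng = _as_rng(seed)
    if isinstance(tree, str):
        tree = dendropy.Tree.get(data=tree, schema="newick")
    out: dict[str, np.ndarray] = {}

    def descend(node, seq):
        for child in node.child_nodes():
            d = child.edge.length or 0.0
            child_seq = evolve_sequence(seq, d, params, rng) if d > 0 else seq
            if child.is_leaf():
                out[child.taxon.label] = child_seq.copy()
            else:
                descend(child, child_seq)

    descend(tree.seed_node, ancestor)
    return out


def pair_at_distance(
    ancestor: np.ndarray,
    d: float,
    params: EvolutionParams | None = None,
    seed=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Two sequences at total distance d (each evolved d/2 from the ancestor)."""
    if d < 0:
        raise ValueError("distance must be >= 0")
    params = params or EvolutionParams()
    rng = _as_rng(seed)
    a = evolve_sequence(ancestor, d / 2.0, params, rng)
    b = evolve_sequence(ancestor, d / 2.0, params, rng)
    return a, b


def simulate_reads(genome: np.ndarray, params: ReadSimParams, seed=None) -> np.ndarray:
    """Uniform short reads with i.i.d. base errors, as an (N, r) uint8 matrix.

    N = round(c*g/r); each erroneous base is replaced by one of the three
    alternatives uniformly.  Linear placement by default (starts in
    [0, g - r]); ``params.circular`` wraps around the origin instead.
    """
    g = genome.size
    r = params.r
    if r > g:
        raise ValueError(f"read length {r} exceeds genome length {g}")
    rng = _as_rng(seed)
    n_reads = int(round(params.c * g / r))
    if n_reads == 0:
        return np.empty((0, r), dtype=np.uint8)
    if params.circular:
        starts = rng.integers(0, g, size=n_reads)
        idx = (starts[:, None] + np.arange(r)) % g
        reads = genome[idx]
    else:
        starts = rng.integers(0, g - r + 1, size=n_reads)
        reads = genome[starts[:, None] + np.arange(r)]
    if params.E > 0:
        err = rng.random(reads.shape) < params.E
        n_err = int(err.sum())
        if n_err:
            reads = reads.copy()
            reads[err] = (reads[err] + rng.integers(1, 4, size=n_err)) % 4
    return reads


# A 12-taxon benchmark topology shaped like the primate clade plus outgroup
# used throughout the validation experiments: a ladder with cherries,
# base-to-tip depth ~0.1 substitutions/site, and short deep internal branches
# (down to 0.002, like the human-gorilla split region) that make topology
# recovery non-trivial.
BENCHMARK_TREE_12 = (
    "(((((((T01:0.067,T02:0.067):0.002,T03:0.069):0.003,T04:0.072):0.004,"
    "(T05:0.066,T06:0.066):0.01):0.006,(T07:0.072,T08:0.072):0.01):0.008,"
    "((T09:0.075,T10:0.075):0.005,T11:0.08):0.01):0.01,T12:0.1);"
)


def benchmark_tree_12(scale: float = 1.0) -> str:
    """The 12-taxon benchmark tree as Newick, optionally rescaled."""
    if scale == 1.0:
        return BENCHMARK_TREE_12
    t = dendropy.Tree.get(data=BENCHMARK_TREE_12, schema="newick")
    for e in t.edges():
        if e.length is not None:
            e.length *= scale
    return t.as_string(schema="newick").strip()


def write_fasta(seqs: dict[str, np.ndarray], path) -> None:
    """Write {name: code array} as FASTA (60-column wrap)."""
    with open(path, "w") as fh:
        for name, codes in seqs.items():
            fh.write(f">{name}\n")
            s = codes_to_seq(codes)
            for i in range(0, len(s), 60):
                fh.write(s[i : i + 60] + "\n")


def write_fastq(reads: np.ndarray, path, name_prefix: str = "read") -> None:
    """Write an (N, r) read matrix as FASTQ with constant quality."""
    qual = "I" * reads.shape[1] if reads.size else ""
    with open(path, "w") as fh:
        for i in range(reads.shape[0]):
            fh.write(f"@{name_prefix}_{i}\n{codes_to_seq(reads[i])}\n+\n{qual}\n")
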