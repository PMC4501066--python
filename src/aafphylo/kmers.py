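"""Canonical k-mer counting and pairwise shared-k-mer statistics.

The distance model consumes only presence/absence of canonical k-mers, so a
taxon is summarised by the set of distinct canonical k-mers seen in its reads
or assembly, plus their copy counts (needed for singleton filtering and for
the k-mer frequency spectrum that feeds the homoplasy model).

K-mers are stored 2-bit packed in int64 arrays (A=0, C=1, G=2, T=3), which
keeps counting and set intersection vectorised; the packed integer order
coincides with lexicographic order over A<C<G<T, so sorted arrays are also
lexicographically sorted.  Any window containing a non-ACGT symbol is skipped
entirely.  The canonical form of a k-mer is the lexicographic minimum of the
k-mer and its reverse complement.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "KmerConfig",
    "KmerTable",
    "PairSharedCounts",
    "KmerSpectrum",
    "canonicalize",
    "revcomp",
    "seq_to_codes",
    "codes_to_seq",
    "canonical_codes",
    "count_kmers",
    "count_kmers_codes",
    "count_kmers_files",
    "shared_counts",
    "spectrum",
    "decode_kmer",
    "write_merged_table",
]

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCATGCA")

# byte value -> 2-bit code; 255 marks anything that is not A/C/G/T
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i  # lowercase (soft-masked) bases are used as-is
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (case-folded to upper)."""
    return seq.upper().translate(_COMPLEMENT)[::-1]


def canonicalize(kmer: str) -> str:
    """Return the canonical form: min(kmer, revcomp(kmer)) lexicographically.

    Raises ValueError for non-ACGT symbols (the caller skips such windows).
    Idempotent: canonicalize(canonicalize(x)) == canonicalize(x).
    """
    up = kmer.upper()
    if any(c not in "ACGT" for c in up):
        raise ValueError(f"non-ACGT symbol in k-mer {kmer!r}")
    rc = up.translate(_COMPLEMENT)[::-1]
    return up if up <= rc else rc


def seq_to_codes(seq: str | bytes) -> np.ndarray:
    """Encode a sequence as uint8 codes (A=0,C=1,G=2,T=3; 255 = ambiguous)."""
    if isinstance(seq, str):
        seq = seq.encode("ascii")
    return _CODE[np.frombuffer(seq, dtype=np.uint8)]


def codes_to_seq(codes: np.ndarray) -> str:
    """Decode uint8 codes back to an ACGT string (255 becomes N)."""
    out = np.full(codes.shape, ord("N"), dtype=np.uint8)
    ok = codes < 4
    out[ok] = _BASES[codes[ok]]
    return out.tobytes().decode("ascii")


def canonical_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """All canonical k-mers of a code array as packed int64, skipping windows
    that contain an ambiguous base.  Vectorised core of the counter."""
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    bad = codes > 3
    clean = np.where(bad, 0, codes).astype(np.int64)
    # Horner accumulation over the k offsets keeps everything as length-n
    # vector ops (much faster than materialising the window matrix)
    fwd = np.zeros(n, dtype=np.int64)
    rc = np.zeros(n, dtype=np.int64)
    for j in range(k):
        fwd = fwd * 4 + clean[j : j + n]
        jj = k - 1 - j
        rc = rc * 4 + (3 - clean[jj : jj + n])
    canon = np.minimum(fwd, rc)
    if bad.any():
        cs = np.concatenate(([0], np.cumsum(bad, dtype=np.int64)))
        valid = (cs[k:] - cs[:-k]) == 0
        canon = canon[valid]
    return canon


def decode_kmer(value: int, k: int) -> str:
    """Unpack an int64-encoded k-mer back to its ACGT string."""
    chars = []
    v = int(value)
    for _ in range(k):
        chars.append("ACGT"[v & 3])
        v >>= 2
    return "".join(reversed(chars))


@dataclass(frozen=True)
class KmerConfig:
    """Counting configuration.

    k : k-mer length in nucleotides (>= 2; <= 31 so packed k-mers fit int64).
    filter_singletons : drop k-mers seen exactly once (error filtering for
        read data; meaningless for assemblies, where a warning is issued
        downstream).
    canonical : collapse each k-mer with its reverse complement (always true
        in this pipeline; exposed for completeness).
    """

    k: int
    filter_singletons: bool = False
    canonical: bool = True

    def __post_init__(self) -> None:
        if not 2 <= self.k <= 31:
            raise ValueError(f"k must be in [2, 31], got {self.k}")


@dataclass
class KmerTable:
    """Distinct canonical k-mers of one taxon with their copy counts.

    `kmers` is sorted ascending (= lexicographic order) and unique;
    `counts` is aligned with it.  If ``filtered`` every count is >= 2.
    """

    taxon_id: str
    k: int
    kmers: np.ndarray
    counts: np.ndarray
    n_bases_seen: int = 0
    filtered: bool = False

    @property
    def n_distinct(self) -> int:
        return int(self.kmers.size)

    def to_dict(self) -> dict[str, int]:
        """Mapping canonical k-mer string -> copy count (small tables only)."""
        return {
            decode_kmer(v, self.k): int(c)
            for v, c in zip(self.kmers.tolist(), self.counts.tolist())
        }

    def filter_singletons(self) -> "KmerTable":
        """Return a copy with count-1 k-mers removed."""
        keep = self.counts >= 2
        return KmerTable(
            taxon_id=self.taxon_id,
            k=self.k,
            kmers=self.kmers[keep],
            counts=self.counts[keep],
            n_bases_seen=self.n_bases_seen,
            filtered=True,
        )


@dataclass(frozen=True)
class PairSharedCounts:
    """Sufficient statistic for one pairwise distance.

    n_s : distinct canonical k-mers present in both taxa (presence/absence).
    n_t : the smaller of the two taxa's distinct-k-mer totals; using the
        minimum compensates the asymmetric k-mer loss caused by deletions.
    """

    taxon_a: str
    taxon_b: str
    n_s: int
    n_t: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_s <= self.n_t:
            raise ValueError(f"need 0 <= n_s <= n_t, got {self.n_s}, {self.n_t}")


@dataclass
class KmerSpectrum:
    """K-mer frequency spectrum: q[j] = fraction of distinct k-mers occurring
    exactly j times (total copy number, j >= 1; q[0] is unused and zero)."""

    k: int
    q: np.ndarray

    def __post_init__(self) -> None:
        if abs(float(self.q[1:].sum()) - 1.0) > 1e-9:
            raise ValueError("spectrum must sum to 1")


def count_kmers_codes(
    code_arrays: Iterable[np.ndarray], cfg: KmerConfig, taxon_id: str = ""
) -> KmerTable:
    """Count canonical k-mers over pre-encoded sequences (uint8 code arrays).

    Accepts any iterable of 1-D code arrays (one per sequence/read); 2-D read
    matrices can be passed through :func:`flatten_read_matrix` first.
    """
    parts: list[np.ndarray] = []
    n_bases = 0
    longest = 0
    for codes in code_arrays:
        n_bases += codes.size
        longest = max(longest, codes.size)
        enc = canonical_codes(codes, cfg.k)
        if enc.size:
            parts.append(enc)
    if n_bases == 0:
        warnings.warn(f"no input sequence for taxon {taxon_id!r}; empty table")
        empty = np.empty(0, dtype=np.int64)
        return KmerTable(taxon_id, cfg.k, empty, empty.copy(), 0, cfg.filter_singletons)
    if longest < cfg.k:
        raise ValueError(
            f"k={cfg.k} exceeds the longest input sequence ({longest} bp) "
            f"for taxon {taxon_id!r}"
        )
    allk = np.concatenate(parts) if parts else np.empty(0, dtype=np.int64)
    kmers, counts = np.unique(allk, return_counts=True)
    table = KmerTable(taxon_id, cfg.k, kmers, counts, n_bases, False)
    if cfg.filter_singletons:
        table = table.filter_singletons()
    return table


def count_kmers(
    sequences: Iterable[str | bytes], cfg: KmerConfig, taxon_id: str = ""
) -> KmerTable:
    """Count canonical k-mers over a stream of nucleotide strings."""
    return count_kmers_codes((seq_to_codes(s) for s in sequences), cfg, taxon_id)


def flatten_read_matrix(reads: np.ndarray) -> np.ndarray:
    """Concatenate an (N, r) uint8 read matrix into one code array, inserting
    an ambiguous separator so windows never span two reads."""
    n, r = reads.shape
    out = np.full((n, r + 1), 255, dtype=np.uint8)
    out[:, :r] = reads
    return out.ravel()


def _open_maybe_gzip(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_sequences(path: str | Path) -> Iterator[str]:
    """Yield sequences from a FASTA or FASTQ file (plain or gzipped)."""
    from Bio import SeqIO

    path = Path(path)
    stem = path.name[:-3] if path.name.endswith(".gz") else path.name
    suffix = Path(stem).suffix.lower()
    fmt = "fastq" if suffix in {".fastq", ".fq"} else "fasta"
    with _open_maybe_gzip(path) as handle:
        for rec in SeqIO.parse(handle, fmt):
            yield str(rec.seq)


def count_kmers_files(
    paths: Sequence[str | Path], cfg: KmerConfig, taxon_id: str = ""
) -> KmerTable:
    """Count over several FASTA/FASTQ files pooled into one taxon.

    Singleton filtering is applied after pooling all of the taxon's files, so
    the result is independent of how reads are split across sequencing runs.
    """

    def gen() -> Iterator[np.ndarray]:
        for p in paths:
            for seq in read_sequences(p):
                yield seq_to_codes(seq)

    return count_kmers_codes(gen(), cfg, taxon_id)


def shared_counts(a: KmerTable, b: KmerTable) -> PairSharedCounts:
    """Presence/absence intersection size and min distinct total for a pair."""
    if a.k != b.k:
        raise ValueError(f"mismatched k: {a.k} vs {b.k}")
    n_s = np.intersect1d(a.kmers, b.kmers, assume_unique=True).size
    n_t = min(a.n_distinct, b.n_distinct)
    return PairSharedCounts(a.taxon_id, b.taxon_id, int(n_s), int(n_t))


def spectrum(table: KmerTable) -> KmerSpectrum:
    """Empirical copy-number spectrum of an unfiltered table."""
    if table.filtered:
        raise ValueError(
            "spectrum requires an unfiltered table; recount without "
            "singleton filtering"
        )
    if table.n_distinct == 0:
        raise ValueError("empty k-mer table has no spectrum")
    binc = np.bincount(table.counts)
    q = binc / table.n_distinct
    q[0] = 0.0
    return KmerSpectrum(k=table.k, q=q)


def write_merged_table(tables: Sequence[KmerTable], path: str | Path) -> None:
    """Write a merged presence/absence TSV: first column the canonical k-mer
    (lexicographically sorted), one 0/1 column per taxon."""
    if len({t.k for t in tables}) != 1:
        raise ValueError("all tables must share the same k")
    k = tables[0].k
    union = np.unique(np.concatenate([t.kmers for t in tables]))
    presence = np.zeros((union.size, len(tables)), dtype=np.uint8)
    for j, t in enumerate(tables):
        idx = np.searchsorted(union, t.kmers)
        presence[idx, j] = 1
    with open(path, "w") as fh:
        fh.write("kmer\t" + "\t".join(t.taxon_id for t in tables) + "\n")
        for i, v in enumerate(union.tolist()):
            fh.write(decode_kmer(v, k) + "\t" + "\t".join(map(str, presence[i])) + "\n")
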