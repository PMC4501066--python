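"""End-to-end run: count -> distance -> tree -> tip-correct -> bootstrap.

A RunConfig (typically loaded from YAML) names each taxon's input files and
sequencing characteristics; the pipeline emits the merged presence/absence
table, the distance matrix with its n_s/n_t sidecar, the fitted Newick, the
tip-corrected Newick, optionally a bootstrap-annotated Newick, and a text
report echoing every parameter.  Identical config + seed give identical
outputs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .distance import build_distance_matrix, write_phylip
from .homoplasy import select_k
from .kmers import KmerConfig, count_kmers_files, write_merged_table
from .sampling import SamplingParams, average_tip_correction
from .tree import fit_tree, trim_tips

log = logging.getLogger("aafphylo")

__all__ = ["TaxonInput", "RunConfig", "run_pipeline", "load_config"]

FILTER_COVERAGE_THRESHOLD = 5.0  # filtering pays off only from ~5-8X coverage


@dataclass
class TaxonInput:
    """One taxon: its sequence files and sequencing characteristics."""

    taxon_id: str
    files: list[str]
    coverage: float = 0.0  # 0 means assembled input
    read_length: float = 100.0
    error_rate: float = 0.0


@dataclass
class RunConfig:
    taxa: list[TaxonInput]
    k: int | None = None
    genome_size: float | None = None  # estimate used to pick k when k is None
    filter_singletons: bool | None = None  # None = decide from coverage
    use_back_correction: bool = False
    tip_correct: bool = True
    bootstrap: int = 0  # parametric bootstrap replicates (0 = off)
    seed: int = 0
    outdir: str = "aaf_out"

    def __post_init__(self) -> None:
        ids = [t.taxon_id for t in self.taxa]
        if len(set(ids)) != len(ids):
            raise ValueError("taxon ids must be unique")


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    taxa = [TaxonInput(**t) for t in raw.pop("taxa")]
    return RunConfig(taxa=taxa, **raw)


def _header(cfg: RunConfig, k: int, filtered: bool) -> str:
    return (
        f"# aafphylo {__version__} k={k} filtered={filtered} seed={cfg.seed}\n"
    )


def run_pipeline(cfg: RunConfig) -> dict[str, Path]:
    """Run every stage; returns a mapping of artifact name -> path."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    # choose k
    k = cfg.k
    select_note = ""
    if k is None:
        if cfg.genome_size is None:
            raise ValueError("either k or a genome-size estimate is required")
        k = select_k(cfg.genome_size)
        select_note = f"k={k} selected for genome size {cfg.genome_size:g}"
        log.info(select_note)

    # decide filtering
    min_cov = min(t.coverage for t in cfg.taxa)
    filtered = cfg.filter_singletons
    auto = filtered is None
    if auto:
        filtered = min_cov >= FILTER_COVERAGE_THRESHOLD and min_cov > 0
    elif filtered and 0 < min_cov < FILTER_COVERAGE_THRESHOLD:
        warnings.warn(
            f"singleton filtering requested at {min_cov:g}X coverage; below "
            f"~{FILTER_COVERAGE_THRESHOLD:g}X it removes many true k-mers"
        )
    if filtered and min_cov == 0:
        warnings.warn("singleton filtering is meaningless for assembled input")

    kcfg = KmerConfig(k=k, filter_singletons=filtered)
    try:
        tables = [
            count_kmers_files(t.files, kcfg, t.taxon_id) for t in cfg.taxa
        ]
    except Exception as exc:  # pragma: no cover - stage naming only
        raise RuntimeError(f"counting stage failed: {exc}") from exc

    table_path = out / "kmer_table.tsv"
    write_merged_table(tables, table_path)
    artifacts["table"] = table_path

    try:
        M = build_distance_matrix(tables, cfg.use_back_correction)
    except Exception as exc:
        raise RuntimeError(f"distance stage failed: {exc}") from exc
    mat_path = out / "distances.phylip"
    write_phylip(M, mat_path, sidecar=str(out / "pair_counts.tsv"))
    artifacts["matrix"] = mat_path

    try:
        tree = fit_tree(M)
    except Exception as exc:
        raise RuntimeError(f"tree stage failed: {exc}") from exc
    tree_path = out / "tree.nwk"
    tree_path.write_text(_header(cfg, k, filtered) + tree.to_newick() + "\n")
    artifacts["tree"] = tree_path

    if cfg.tip_correct and all(t.coverage > 0 for t in cfg.taxa):
        params = [
            SamplingParams(t.coverage, t.read_length, t.error_rate, k, filtered)
            for t in cfg.taxa
        ]
        n_t = [tab.n_distinct for tab in tables]
        corr = average_tip_correction(params, n_t, [t.taxon_id for t in cfg.taxa])
        trimmed = trim_tips(tree, corr)
        trimmed_path = out / "tree_tipcorrected.nwk"
        trimmed_path.write_text(
            _header(cfg, k, filtered) + trimmed.to_newick() + "\n"
        )
        artifacts["tree_tipcorrected"] = trimmed_path

    if cfg.bootstrap > 0 and all(t.coverage > 0 for t in cfg.taxa):
        from .bootstrap import BootstrapConfig, parametric_bootstrap

        params_by = {
            t.taxon_id: SamplingParams(
                t.coverage, t.read_length, t.error_rate, k, filtered
            )
            for t in cfg.taxa
        }
        bcfg = BootstrapConfig(B=cfg.bootstrap, seed=cfg.seed)
        try:
            support, annotated = parametric_bootstrap(M, tree, params_by, bcfg)
        except Exception as exc:
            raise RuntimeError(f"bootstrap stage failed: {exc}") from exc
        boot_path = out / "tree_bootstrap.nwk"
        boot_path.write_text(
            _header(cfg, k, filtered)
            + annotated.to_newick(support_as_percent_of=support.B)
            + "\n"
        )
        artifacts["tree_bootstrap"] = boot_path
        sup_path = out / "support.tsv"
        with open(sup_path, "w") as fh:
            fh.write("bipartition\tstage1\tstage2\n")
            for m in sorted(set(support.stage1) | set(support.stage2)):
                fh.write(
                    f"{support.describe(m)}\t{support.stage1.get(m, 0)}"
                    f"\t{support.stage2.get(m, 0)}\n"
                )
        artifacts["support"] = sup_path

    report = out / "report.txt"
    with open(report, "w") as fh:
        fh.write(_header(cfg, k, filtered))
        fh.write(f"taxa: {', '.join(t.taxon_id for t in cfg.taxa)}\n")
        fh.write(f"k: {k}\nfiltered: {filtered} (auto={auto})\n")
        if select_note:
            fh.write(select_note + "\n")
        fh.write(f"back_correction: {cfg.use_back_correction}\n")
        fh.write(f"bootstrap replicates: {cfg.bootstrap}\nseed: {cfg.seed}\n")
        for t, tab in zip(cfg.taxa, tables):
            fh.write(
                f"  {t.taxon_id}: {tab.n_distinct} distinct {k}-mers from "
                f"{tab.n_bases_seen} bases\n"
            )
    artifacts["report"] = report
    return artifacts
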