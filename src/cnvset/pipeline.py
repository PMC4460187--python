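"""End-to-end orchestration: QC -> annotation -> enrichment batteries ->
permutation -> minimal set -> conditional scan -> burden -> report.

A run is driven by one YAML config and one seed, and is deterministic: the
machine-readable TSVs it writes are byte-identical across repeat runs.  A
human-readable summary rounds p-values to 2 significant figures and odds
ratios to 2 decimals; the TSVs keep full precision.
"""

from __future__ import annotations

import logging
import platform
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .conditional import (
    burden_analysis,
    burden_to_frame,
    conditional_scan,
    minimal_set_selection,
)
from .enrichment import EnrichmentResult, results_to_frame, run_battery
from .genesets import annotate, build_union_set, load_gmt
from .io import (
    read_bed_regions,
    read_cnv_table,
    read_gene_table,
    read_probe_map,
    write_cnv_table,
)
from .permutation import excess_enrichment_test, excess_to_frame
from .qc import remove_known_loci, run_qc

log = logging.getLogger(__name__)

ANALYSES = ("combined", "deletion", "duplication")


@dataclass
class RunConfig:
    cnv_path: str
    gene_path: str
    sets_path: str
    out_dir: str
    n_samples: int
    probe_path: str | None = None
    lcr_path: str | None = None
    known_loci_path: str | None = None
    extra_sets_path: str | None = None   # e.g. a GO/MP battery for the conditional scan
    coords: str = "bed"
    analyses: tuple[str, ...] = ANALYSES
    n_tests: int | None = None           # default: n_sets * n_analyses
    extra_n_tests: int | None = None
    alpha_adj: float = 0.05
    stepwise_alpha: float = 0.05
    thresholds: tuple[float, ...] = (0.01, 0.001)
    n_perm: int = 1000
    perm_adj_factor: int | None = None
    seed: int = 0
    min_len: int = 100_000
    min_probes: int = 15
    max_freq: float = 0.01
    recip_overlap: float = 0.5
    max_lcr_overlap: float = 0.5
    run_permutation: bool = True
    run_known_loci: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        cfg = cls(**raw)
        for p in (cfg.cnv_path, cfg.gene_path, cfg.sets_path):
            if not Path(p).exists():
                raise FileNotFoundError(p)
        return cfg


def _subset(rows: pd.DataFrame, analysis: str) -> pd.DataFrame:
    if analysis == "combined":
        return rows
    return rows.loc[rows["copy_state"] == analysis].reset_index(drop=True)


def run_full(cfg: RunConfig) -> dict[str, object]:
    """Execute the full analysis sequence and write the report bundle.

    Returns the in-memory results keyed by artifact name.  Any stage failure
    raises with the stage name attached.
    """
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stage = "load"
    bundle: dict[str, object] = {}
    try:
        calls = read_cnv_table(cfg.cnv_path, coords=cfg.coords)
        genes = read_gene_table(cfg.gene_path)
        sets = load_gmt(cfg.sets_path)
        probes = read_probe_map(cfg.probe_path) if cfg.probe_path else None
        lcr = read_bed_regions(cfg.lcr_path) if cfg.lcr_path else None
        loci = (
            read_bed_regions(cfg.known_loci_path) if cfg.known_loci_path else None
        )
        extra_sets = load_gmt(cfg.extra_sets_path) if cfg.extra_sets_path else None

        stage = "qc"
        clean = run_qc(
            calls, n_samples=cfg.n_samples, lcr=lcr, probes=probes,
            min_len=cfg.min_len, min_probes=cfg.min_probes,
            max_freq=cfg.max_freq, recip_overlap=cfg.recip_overlap,
            max_lcr_overlap=cfg.max_lcr_overlap,
        )

        stage = "annotate"
        rows = annotate(clean, genes)
        write_cnv_table(rows, out_dir / "cnvs_annotated.tsv")

        n_tests = cfg.n_tests if cfg.n_tests is not None else len(sets) * len(cfg.analyses)
        battery_results: dict[str, list[EnrichmentResult]] = {}
        for analysis in cfg.analyses:
            stage = f"enrichment[{analysis}]"
            sub = _subset(rows, analysis)
            res = run_battery(sub, sets, n_tests=n_tests, analysis=analysis)
            battery_results[analysis] = res
            results_to_frame(res).to_csv(
                out_dir / f"enrichment_{analysis}.tsv", sep="\t", index=False
            )
        bundle["enrichment"] = battery_results

        if cfg.run_permutation:
            excess_all = []
            for analysis in cfg.analyses:
                stage = f"permutation[{analysis}]"
                sub = _subset(rows, analysis)
                excess_all.extend(
                    excess_enrichment_test(
                        sub, sets, thresholds=cfg.thresholds, n_perm=cfg.n_perm,
                        seed=np.random.SeedSequence([cfg.seed, ANALYSES.index(analysis)]),
                        analysis=analysis,
                        p_adj_factor=cfg.perm_adj_factor
                        or len(cfg.thresholds) * len(cfg.analyses),
                    )
                )
            excess_to_frame(excess_all).to_csv(
                out_dir / "excess_summary.tsv", sep="\t", index=False
            )
            bundle["excess"] = excess_all

        if cfg.run_known_loci and loci is not None:
            stage = "known_loci"
            kept = remove_known_loci(rows, loci)
            for analysis in cfg.analyses:
                sub = _subset(kept, analysis)
                res = run_battery(sub, sets, n_tests=n_tests, analysis=analysis)
                results_to_frame(res).to_csv(
                    out_dir / f"enrichment_{analysis}_minus_known_loci.tsv",
                    sep="\t", index=False,
                )
            bundle["minus_known_loci_rows"] = kept

        by_name = {s.name: s for s in sets}
        minimal: dict[str, tuple[str, ...]] = {}
        for analysis in cfg.analyses:
            stage = f"minimal_set[{analysis}]"
            sub = _subset(rows, analysis)
            passing = [
                by_name[r.set_name]
                for r in sorted(battery_results[analysis], key=lambda r: r.p_one_sided)
                if r.p_adj is not None and r.p_adj < cfg.alpha_adj
            ]
            sel = minimal_set_selection(
                sub, passing, alpha=cfg.stepwise_alpha, analysis=analysis
            )
            minimal[analysis] = sel.selected
            pd.DataFrame(
                {"analysis": analysis, "step": i + 1, "set_name": nm}
                for i, nm in enumerate(sel.selected)
            ).to_csv(out_dir / f"minimal_set_{analysis}.tsv", sep="\t", index=False)
            bundle[f"minimal_set_{analysis}"] = sel

            if extra_sets is not None:
                stage = f"conditional_scan[{analysis}]"
                cond = [by_name[nm] for nm in sel.selected]
                extra_n = cfg.extra_n_tests or len(extra_sets) * len(cfg.analyses)
                scan = conditional_scan(
                    sub, extra_sets, cond, n_tests=extra_n, analysis=analysis
                )
                results_to_frame(scan).to_csv(
                    out_dir / f"conditional_scan_{analysis}.tsv", sep="\t", index=False
                )

        stage = "burden"
        burden_frames = []
        for analysis in cfg.analyses:
            sub = _subset(rows, analysis)
            cns = None
            try:
                cns = build_union_set(
                    battery_results[analysis], sets,
                    alpha_adj=cfg.alpha_adj, analysis=analysis,
                )
            except ValueError:
                log.info("no associated set for %s; CNS union burden skipped", analysis)
            preds = ["size_kb", "n_genes_total"] + (["n_genes_cns_sz"] if cns else [])
            res = burden_analysis(sub, tuple(preds), cns_set=cns, analysis=analysis)
            res += burden_analysis(
                sub, ("n_genes_total",), conditioning=("size_kb",),
                cns_set=cns, analysis=analysis,
            )
            res += burden_analysis(
                sub, ("size_kb",), conditioning=("n_genes_total",),
                cns_set=cns, analysis=analysis,
            )
            if cns is not None:
                res += burden_analysis(
                    sub, ("n_genes_cns_sz",), conditioning=("n_genes_total",),
                    cns_set=cns, analysis=analysis,
                )
                res += burden_analysis(
                    sub, ("n_genes_total",), conditioning=("n_genes_cns_sz",),
                    cns_set=cns, analysis=analysis,
                )
            burden_frames.append(burden_to_frame(res))
        burden_df = pd.concat(burden_frames, ignore_index=True)
        burden_df.to_csv(out_dir / "burden.tsv", sep="\t", index=False)
        bundle["burden"] = burden_df

        stage = "top_genes"
        from .enrichment import extract_top_genes

        top_frames = []
        for analysis in cfg.analyses:
            sub = _subset(rows, analysis)
            tg = extract_top_genes(
                battery_results[analysis], sub, sets, alpha_adj=cfg.alpha_adj
            )
            tg.insert(0, "analysis", analysis)
            top_frames.append(tg)
        top_df = pd.concat(top_frames, ignore_index=True)
        top_df.to_csv(out_dir / "top_genes.tsv", sep="\t", index=False)
        bundle["top_genes"] = top_df

        stage = "log"
        _write_run_log(cfg, out_dir, n_qc=len(rows))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return bundle


def _write_run_log(cfg: RunConfig, out_dir: Path, n_qc: int) -> None:
    lines = [
        f"cnvset {__version__} (python {platform.python_version()}, "
        f"numpy {np.__version__}, pandas {pd.__version__})",
        f"seed: {cfg.seed}",
        f"CNVs after QC: {n_qc}",
    ]
    for key, val in sorted(vars(cfg).items()):
        lines.append(f"{key}: {val}")
    (out_dir / "run_log.txt").write_text("\n".join(lines) + "\n")


def format_p(p: float) -> str:
    """Two-significant-figure p for the human-readable report."""
    return f"{p:.2g}"
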