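"""Stepwise minimal-set selection, conditional scans, and burden analyses.

The "minimal set" is the smallest ordered collection of gene sets that, once
entered as covariates, leaves no residual set enrichment at the stepwise
threshold: at each step the candidate with the most significant residual
enrichment (conditioning on all previously selected sets) is added, until no
remaining candidate has residual p below alpha.

Burden analyses ask whether CNV size, the total number of genes hit, or the
number of hits in an associated union set predicts case status, each tested
one-sided by the same signed-root deviance statistic, optionally conditioning
on the other predictors.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .enrichment import (
    Design,
    EnrichmentResult,
    bonferroni,
    set_enrichment_test,
)
from .genesets import GeneSet, hit_count_column

BURDEN_PREDICTORS = ("size_kb", "n_genes_total", "n_genes_cns_sz")


@dataclass(frozen=True)
class MinimalSetResult:
    """Audit trail of a stepwise selection."""

    analysis: str
    selected: tuple[str, ...]
    step_pvalues: tuple[dict[str, float], ...]  # residual p per candidate, per step
    stopping_reason: str


@dataclass(frozen=True)
class BurdenResult:
    """One burden predictor's one-sided test."""

    analysis: str
    predictor: str
    conditioning: tuple[str, ...]
    beta: float
    p_one_sided: float
    degenerate: bool = False


def minimal_set_selection(
    rows: pd.DataFrame,
    candidate_sets: list[GeneSet],
    alpha: float = 0.05,
    analysis: str = "combined",
) -> MinimalSetResult:
    """Greedy forward selection of the sets capturing the enrichment signal.

    Ties at a step are broken by smaller p, then lexicographic set name.
    All per-step residual p-values are retained for audit.
    """
    remaining = {s.name: s for s in candidate_sets}
    if not remaining:
        return MinimalSetResult(
            analysis=analysis, selected=(), step_pvalues=(),
            stopping_reason="no candidates",
        )
    selected: list[GeneSet] = []
    steps: list[dict[str, float]] = []
    reason = "all candidates selected"
    while remaining:
        design = Design(rows, conditioning=tuple(selected))
        pvals = {
            name: set_enrichment_test(rows, s, design=design).p_one_sided
            for name, s in remaining.items()
        }
        steps.append(pvals)
        best = min(pvals, key=lambda nm: (pvals[nm], nm))
        if pvals[best] >= alpha:
            reason = "no residual association"
            break
        selected.append(remaining.pop(best))
    return MinimalSetResult(
        analysis=analysis,
        selected=tuple(s.name for s in selected),
        step_pvalues=tuple(steps),
        stopping_reason=reason,
    )


def conditional_scan(
    rows: pd.DataFrame,
    scan_sets: list[GeneSet],
    conditioning: list[GeneSet],
    n_tests: int | None = None,
    analysis: str = "combined",
) -> list[EnrichmentResult]:
    """Test each scan set with the conditioning sets held in model (a);
    Bonferroni-adjust over ``n_tests`` (default: the scan size)."""
    design = Design(rows, conditioning=tuple(conditioning))
    n = n_tests if n_tests is not None else len(scan_sets)
    out = []
    for s in scan_sets:
        r = set_enrichment_test(rows, s, analysis=analysis, design=design)
        out.append(replace(r, p_adj=bonferroni(r.p_one_sided, n)))
    return out


def burden_analysis(
    rows: pd.DataFrame,
    predictors: tuple[str, ...] = ("size_kb", "n_genes_total"),
    conditioning: tuple[str, ...] = (),
    cns_set: GeneSet | None = None,
    analysis: str = "combined",
) -> list[BurdenResult]:
    """One-sided tests of burden predictors against case status.

    The base model always contains the stratum factor plus the
    ``conditioning`` predictors; each requested predictor is then added and
    tested by signed-root deviance (one-sided toward case excess).  The
    ``n_genes_cns_sz`` predictor counts hits in ``cns_set`` (the union of
    associated sets) and requires it to be supplied.
    """
    rows = rows.reset_index(drop=True)
    values: dict[str, np.ndarray] = {}
    for name in set(predictors) | set(conditioning):
        if name == "n_genes_cns_sz":
            if cns_set is None:
                raise ValueError("n_genes_cns_sz requested but no cns_set supplied")
            values[name] = hit_count_column(rows, cns_set).astype(float)
        elif name in ("size_kb", "n_genes_total"):
            values[name] = rows[name].to_numpy(dtype=float)
        else:
            raise ValueError(f"unknown burden predictor {name!r}")

    work = rows.copy()
    for name, col in values.items():
        work[f"_pred[{name}]"] = col
    base_cols = tuple(f"_pred[{name}]" for name in conditioning)
    design = Design(work, base_covariates=base_cols)

    out = []
    for name in predictors:
        col = design.rows[f"_pred[{name}]"].to_numpy(dtype=float)
        # a predictor lying in the span of the base design is unidentifiable
        coef, *_ = np.linalg.lstsq(design.X, col, rcond=None)
        resid = col - design.X @ coef
        scale = max(1.0, float(np.max(np.abs(col))))
        if np.max(np.abs(resid)) < 1e-8 * scale:
            out.append(
                BurdenResult(
                    analysis=analysis, predictor=name,
                    conditioning=tuple(conditioning), beta=0.0,
                    p_one_sided=0.5, degenerate=True,
                )
            )
            continue
        dd, beta, _, p, degen = design.test_column(col)
        out.append(
            BurdenResult(
                analysis=analysis, predictor=name,
                conditioning=tuple(conditioning), beta=beta,
                p_one_sided=p, degenerate=degen,
            )
        )
    return out


def burden_to_frame(results: list[BurdenResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "analysis": [r.analysis for r in results],
            "predictor": [r.predictor for r in results],
            "conditioning": [",".join(r.conditioning) for r in results],
            "beta": [r.beta for r in results],
            "p": [r.p_one_sided for r in results],
            "degenerate": [r.degenerate for r in results],
        }
    )
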