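"""Gene-set enrichment by nested logistic deviance testing.

For each annotated CNV the probability of originating from a case is
modelled by logistic regression:

    (a)  logit pr(case) = stratum + size_kb + n_genes_total [+ conditioning]
    (b)  model (a)      + n_genes_in_set

where ``stratum`` is the study x genotyping-chip factor.  The enrichment
statistic is the deviance drop from (a) to (b); since a set can only be
*enriched* in case CNVs in one direction, the test is one-sided via the
signed root of the deviance change,

    z = sign(beta_set) * sqrt(deviance_a - deviance_b),   p = 1 - Phi(z),

which is exact under the chi-square(1) asymptotics of the likelihood-ratio
test and gives p = 0.5 at beta_set = 0.  Odds ratios are exp(beta_set) per
additional set gene hit, with Wald 95% intervals.

Single-gene tests are the same machinery with a singleton set (the covariate
becomes the 0/1 indicator of the gene being hit).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from ._glm import MAX_ITER, IrlsFit, irls_logistic
from .genesets import GeneSet, hit_count_column

log = logging.getLogger(__name__)

Z975 = 1.959963984540054  # Phi^-1(0.975)


@dataclass(frozen=True)
class ModelFit:
    """A fitted logistic model with named coefficients."""

    coefficients: dict[str, float]
    deviance: float
    converged: bool
    n_iter: int


@dataclass(frozen=True)
class EnrichmentResult:
    """One gene set's enrichment test in one analysis."""

    set_name: str
    analysis: str
    delta_deviance: float
    beta_set: float
    p_one_sided: float
    p_adj: float | None
    odds_ratio: float
    ci95: tuple[float, float]
    n_case_cnv: int
    n_ctrl_cnv: int
    degenerate: bool = False


class Design:
    """Design matrix for the nested models, built once per analysis.

    Rows from strata containing only cases or only controls are dropped
    (their stratum indicator is unidentifiable); constant covariate columns
    are dropped with a warning.  Because a within-stratum label permutation
    preserves each stratum's class counts, the same rows survive for every
    permuted label vector, so a Design can be reused across permutations.
    """

    def __init__(
        self,
        rows: pd.DataFrame,
        base_covariates: tuple[str, ...] = ("size_kb", "n_genes_total"),
        conditioning: tuple[GeneSet, ...] = (),
    ):
        rows = rows.reset_index(drop=True)
        y = rows["phenotype"].to_numpy(dtype=float)
        if y.min() == y.max():
            raise ValueError("need at least one case and one control CNV")
        stratum = (rows["study"].astype(str) + "|" + rows["chip"].astype(str)).to_numpy()
        keep = np.ones(len(rows), dtype=bool)
        for lev in np.unique(stratum):
            mask = stratum == lev
            if y[mask].min() == y[mask].max():
                warnings.warn(
                    f"stratum {lev!r} has a single phenotype class; its rows are dropped",
                    stacklevel=3,
                )
                keep &= ~mask
        self.rows = rows.loc[keep].reset_index(drop=True)
        self.y = y[keep]
        if len(self.y) == 0 or self.y.min() == self.y.max():
            raise ValueError("no identifiable stratum with both cases and controls")
        stratum = stratum[keep]
        levels = sorted(np.unique(stratum))
        cols: list[np.ndarray] = [np.ones(len(self.y))]
        names: list[str] = ["const"]
        for lev in levels[1:]:  # first level is the reference
            cols.append((stratum == lev).astype(float))
            names.append(f"stratum[{lev}]")
        for cov in base_covariates:
            cols.append(self.rows[cov].to_numpy(dtype=float))
            names.append(cov)
        for cset in conditioning:
            cols.append(hit_count_column(self.rows, cset).astype(float))
            names.append(f"hits[{cset.name}]")
        X = np.column_stack(cols)
        const_cols = [
            j for j in range(1, X.shape[1]) if np.ptp(X[:, j]) == 0.0
        ]
        if const_cols:
            warnings.warn(
                f"constant covariate(s) dropped: {[names[j] for j in const_cols]}",
                stacklevel=3,
            )
            keep_cols = [j for j in range(X.shape[1]) if j not in const_cols]
            X = X[:, keep_cols]
            names = [names[j] for j in keep_cols]
        self.X = X
        self.names = names
        self.n_case = int(self.y.sum())
        self.n_ctrl = int(len(self.y) - self.y.sum())
        self._null_fit: IrlsFit | None = None

    def fit_null(self, y: np.ndarray | None = None) -> IrlsFit:
        """Fit model (a); cached for the real label vector."""
        if y is None:
            if self._null_fit is None:
                self._null_fit = irls_logistic(self.X, self.y)
            return self._null_fit
        return irls_logistic(self.X, y, compute_cov=False)

    def test_column(
        self,
        col: np.ndarray,
        y: np.ndarray | None = None,
        fit_a: IrlsFit | None = None,
        need_se: bool = True,
    ) -> tuple[float, float, float, float, bool]:
        """One-sided nested test of adding ``col`` to model (a).

        Returns (delta_deviance, beta, se, p_one_sided, degenerate).
        """
        yv = self.y if y is None else y
        if np.ptp(col) == 0.0:
            return 0.0, 0.0, np.inf, 0.5, True
        if fit_a is None:
            fit_a = self.fit_null(y)
        Xb = np.column_stack([self.X, col])
        beta0 = np.append(fit_a.beta, 0.0)
        fit_b = irls_logistic(Xb, yv, beta0=beta0, compute_cov=need_se)
        dd = max(fit_a.deviance - fit_b.deviance, 0.0)
        beta = float(fit_b.beta[-1])
        se = fit_b.se(Xb.shape[1] - 1) if need_se else np.nan
        z = np.sign(beta) * np.sqrt(dd)
        p = float(stats.norm.sf(z))
        return dd, beta, se, p, False


def fit_logistic(
    rows: pd.DataFrame,
    covariates: tuple[str, ...] = ("size_kb", "n_genes_total"),
    conditioning: tuple[GeneSet, ...] = (),
) -> ModelFit:
    """Maximum-likelihood logistic fit of case status on the named covariates
    (plus stratum indicators), by IRLS.

    Convergence is declared when max |score| < 1e-8, with a 50-iteration cap
    (hitting the cap is logged; the deviance at the cap is still valid for
    nested comparisons).
    """
    design = Design(rows, base_covariates=covariates, conditioning=conditioning)
    fit = design.fit_null()
    if not fit.converged:
        log.warning("IRLS hit the %d-iteration cap (separation likely)", MAX_ITER)
    return ModelFit(
        coefficients=dict(zip(design.names, fit.beta)),
        deviance=fit.deviance,
        converged=fit.converged,
        n_iter=fit.n_iter,
    )


def set_enrichment_test(
    rows: pd.DataFrame,
    geneset: GeneSet,
    conditioning_sets: tuple[GeneSet, ...] = (),
    analysis: str = "combined",
    design: Design | None = None,
) -> EnrichmentResult:
    """One-sided nested-deviance test of a gene set's enrichment in case CNVs.

    ``rows`` must already be restricted to the analysis of interest
    (combined / deletions / duplications).  A precomputed ``design`` (from the
    same rows and conditioning sets) can be passed to amortize setup across a
    battery of sets.
    """
    if design is None:
        design = Design(rows, conditioning=tuple(conditioning_sets))
    col = hit_count_column(design.rows, geneset).astype(float)
    dd, beta, se, p, degen = design.test_column(col)
    if degen:
        return EnrichmentResult(
            set_name=geneset.name, analysis=analysis, delta_deviance=0.0,
            beta_set=0.0, p_one_sided=0.5, p_adj=None, odds_ratio=1.0,
            ci95=(0.0, np.inf), n_case_cnv=design.n_case, n_ctrl_cnv=design.n_ctrl,
            degenerate=True,
        )
    return EnrichmentResult(
        set_name=geneset.name, analysis=analysis, delta_deviance=dd,
        beta_set=beta, p_one_sided=p, p_adj=None, odds_ratio=float(np.exp(beta)),
        ci95=(float(np.exp(beta - Z975 * se)), float(np.exp(beta + Z975 * se))),
        n_case_cnv=design.n_case, n_ctrl_cnv=design.n_ctrl,
    )


def single_gene_test(
    rows: pd.DataFrame,
    gene: str,
    conditioning_sets: tuple[GeneSet, ...] = (),
    analysis: str = "combined",
    design: Design | None = None,
) -> EnrichmentResult:
    """Enrichment test with the 'set' restricted to a single gene (the hit
    covariate becomes a 0/1 indicator)."""
    return set_enrichment_test(
        rows, GeneSet(name=gene, genes=frozenset([gene])),
        conditioning_sets=conditioning_sets, analysis=analysis, design=design,
    )


def bonferroni(p: float, n_tests: int) -> float:
    """min(1, p * n_tests)."""
    if not 0.0 < p <= 1.0:
        raise ValueError("p must lie in (0, 1]")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return min(1.0, p * n_tests)


def run_battery(
    rows: pd.DataFrame,
    sets: list[GeneSet],
    n_tests: int | None = None,
    conditioning_sets: tuple[GeneSet, ...] = (),
    analysis: str = "combined",
) -> list[EnrichmentResult]:
    """Test every set in a battery against the same rows; Bonferroni-adjust
    over ``n_tests`` (default: the battery size)."""
    design = Design(rows, conditioning=tuple(conditioning_sets))
    n = n_tests if n_tests is not None else len(sets)
    out = []
    for s in sets:
        r = set_enrichment_test(rows, s, analysis=analysis, design=design)
        out.append(replace(r, p_adj=bonferroni(r.p_one_sided, n)))
    return out


def extract_top_genes(
    results: list[EnrichmentResult],
    rows: pd.DataFrame,
    sets: list[GeneSet],
    alpha_adj: float = 0.05,
    alpha_gene: float = 0.05,
) -> pd.DataFrame:
    """For each set surviving correction, the member genes with uncorrected
    single-gene p below ``alpha_gene``, sorted by set then p."""
    by_name = {s.name: s for s in sets}
    design = Design(rows)
    gene_p: dict[str, float] = {}
    records = []
    for r in results:
        if r.p_adj is None or r.p_adj >= alpha_adj:
            continue
        for gene in sorted(by_name[r.set_name].genes):
            if gene not in gene_p:
                gr = single_gene_test(rows, gene, design=design)
                gene_p[gene] = gr.p_one_sided
            if gene_p[gene] < alpha_gene:
                records.append((r.set_name, gene, gene_p[gene]))
    df = pd.DataFrame(records, columns=["set_name", "gene_id", "p"])
    return df.sort_values(["set_name", "p", "gene_id"]).reset_index(drop=True)


def results_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    """Tabulate enrichment results (one row per set)."""
    return pd.DataFrame(
        {
            "set_name": [r.set_name for r in results],
            "analysis": [r.analysis for r in results],
            "delta_deviance": [r.delta_deviance for r in results],
            "beta_set": [r.beta_set for r in results],
            "p": [r.p_one_sided for r in results],
            "p_adj": [r.p_adj for r in results],
            "OR": [r.odds_ratio for r in results],
            "ci_low": [r.ci95[0] for r in results],
            "ci_high": [r.ci95[1] for r in results],
            "n_case_cnv": [r.n_case_cnv for r in results],
            "n_ctrl_cnv": [r.n_ctrl_cnv for r in results],
            "degenerate": [r.degenerate for r in results],
        }
    )
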