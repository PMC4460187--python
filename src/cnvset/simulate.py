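"""Synthetic case-control CNV worlds with known embedded effects.

The generator produces a genome (non-overlapping genes, a jittered probe
grid, low-copy-repeat regions), a battery of overlapping gene sets, and a
per-stratum CNV table whose phenotypes are drawn from the same logistic
model the analysis fits:

    logit pr(case) = stratum intercept + b_size * size_kb
                     + b_total * n_genes_total
                     + sum_s beta_s * (genes hit in set s)

so that estimated set effects can be checked against the embedded truth.
Covariates are computed by the real annotation code, never shortcut.

Default parameters emulate the shape of a large schizophrenia CNV study at
desk scale: three study x chip strata (a large Illumina stratum and two
Affymetrix strata) totalling ~4,000 large rare CNVs at an overall case
fraction of 0.437; 40% deletions; truncated-lognormal CNV lengths with a
100 kb floor, duplications running larger than deletions; 134 gene sets with
lognormal sizes and hub-driven pairwise overlap over a 1,600-gene, 100 Mb
genome.  Phenotype is assigned per CNV (matching the CNV-level regression);
``per_individual=True`` instead shares one drawn phenotype across all of a
sample's CNVs, to probe the independence assumption.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .genesets import GeneIndex, GeneSet, annotate, hit_count_column


@dataclass
class StratumSpec:
    study: str
    chip: str
    n_case_cnv: int
    n_ctrl_cnv: int

    @property
    def n_cnv(self) -> int:
        return self.n_case_cnv + self.n_ctrl_cnv

    @property
    def case_fraction(self) -> float:
        return self.n_case_cnv / self.n_cnv


@dataclass
class SimConfig:
    """Parameters of the simulated world (defaults: the stated world above)."""

    seed: int = 0
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 40_000_000, "chr2": 30_000_000, "chr3": 30_000_000}
    )
    n_genes: int = 1600
    gene_len_median: float = 20_000.0
    gene_len_sigma: float = 0.8
    probe_spacing: int = 5_000
    probe_jitter: int = 1_000
    lcr_fraction: float = 0.02
    lcr_region_len: int = 50_000
    n_sets: int = 134
    set_size_median: float = 25.0
    set_size_sigma: float = 0.9
    set_size_min: int = 5
    set_size_max: int = 300
    hub_fraction: float = 0.2
    hub_size: int = 200
    strata: list[StratumSpec] = field(
        default_factory=lambda: [
            StratumSpec("CLOZUK", "Illumina", 1050, 1350),
            StratumSpec("MGS", "Affy6.0", 440, 560),
            StratumSpec("ISC", "Affy5.0", 260, 340),
        ]
    )
    deletion_fraction: float = 0.40
    cnv_len_median: dict[str, float] = field(
        default_factory=lambda: {"deletion": 160_000.0, "duplication": 250_000.0}
    )
    cnv_len_sigma: dict[str, float] = field(
        default_factory=lambda: {"deletion": 0.7, "duplication": 0.7}
    )
    cnv_min_len: int = 100_000
    b_size: float = 5e-4       # log-odds per kb
    b_total: float = 0.03      # log-odds per gene hit
    set_effects: dict[str, float] = field(default_factory=dict)  # name -> log-odds per set gene hit
    per_individual: bool = False
    cnvs_per_sample: int = 1


@dataclass
class TruthRecord:
    """What the generator embedded, for recovery checks."""

    seed: int
    set_betas: dict[str, float]
    stratum_intercepts: dict[str, float]
    linear_predictor: np.ndarray
    realized_counts: dict[str, tuple[int, int]]  # stratum -> (n_case, n_ctrl)

    def to_json(self, path: str | Path) -> None:
        d = {
            "seed": self.seed,
            "set_betas": self.set_betas,
            "stratum_intercepts": self.stratum_intercepts,
            "linear_predictor": [float(v) for v in self.linear_predictor],
            "realized_counts": {k: list(v) for k, v in self.realized_counts.items()},
        }
        Path(path).write_text(json.dumps(d, indent=1))


def _lognormal(rng: np.random.Generator, median: float, sigma: float, size: int) -> np.ndarray:
    return np.exp(rng.normal(np.log(median), sigma, size=size))


def generate_genome(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, dict[str, np.ndarray], pd.DataFrame]:
    """Genes (non-overlapping, uniformly spread), probe map, LCR regions."""
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    total_len = sum(cfg.chrom_lengths.values())
    genes = []
    gidx = 0
    for chrom, clen in cfg.chrom_lengths.items():
        n_c = int(round(cfg.n_genes * clen / total_len))
        lengths = np.round(
            _lognormal(rng, cfg.gene_len_median, cfg.gene_len_sigma, n_c)
        ).astype(np.int64)
        lengths = np.clip(lengths, 200, None)
        free = clen - int(lengths.sum())
        if free <= n_c:
            raise ValueError(f"genes cannot fit on {chrom}")
        # drop genes into the free space: random gaps, then cumulative placement
        gaps = rng.dirichlet(np.ones(n_c + 1)) * free
        pos = 0
        for i in range(n_c):
            pos += int(gaps[i])
            genes.append((f"G{gidx:05d}", chrom, pos, pos + int(lengths[i])))
            pos += int(lengths[i])
            gidx += 1
    gene_df = pd.DataFrame(genes, columns=["gene_id", "chrom", "start", "end"])

    probes: dict[str, np.ndarray] = {}
    for chrom, clen in cfg.chrom_lengths.items():
        grid = np.arange(cfg.probe_spacing // 2, clen, cfg.probe_spacing)
        jitter = rng.integers(-cfg.probe_jitter, cfg.probe_jitter + 1, size=len(grid))
        probes[chrom] = np.unique(np.clip(grid + jitter, 0, clen - 1))

    lcr_rows = []
    for chrom, clen in cfg.chrom_lengths.items():
        n_reg = int(round(cfg.lcr_fraction * clen / cfg.lcr_region_len))
        starts = np.sort(rng.integers(0, clen - cfg.lcr_region_len, size=n_reg))
        for s in starts:
            lcr_rows.append((chrom, int(s), int(s) + cfg.lcr_region_len))
    lcr = pd.DataFrame(lcr_rows, columns=["chrom", "start", "end"])
    return gene_df, probes, lcr


def generate_gene_sets(
    cfg: SimConfig,
    genes: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> list[GeneSet]:
    """Overlapping sets: a fraction of each set is drawn from a shared hub
    pool, the rest uniformly, giving a controlled expected pairwise overlap
    (see ``expected_pairwise_jaccard``)."""
    rng = np.random.default_rng(cfg.seed + 1) if rng is None else rng
    ids = genes["gene_id"].to_numpy()
    if cfg.n_sets == 0:
        return []
    hub = rng.choice(ids, size=min(cfg.hub_size, len(ids)), replace=False)
    non_hub = np.setdiff1d(ids, hub)
    sizes = np.clip(
        np.round(_lognormal(rng, cfg.set_size_median, cfg.set_size_sigma, cfg.n_sets)),
        cfg.set_size_min,
        min(cfg.set_size_max, len(ids)),
    ).astype(int)
    sets = []
    for k, size in enumerate(sizes):
        n_hub = min(int(round(cfg.hub_fraction * size)), len(hub))
        n_rest = min(size - n_hub, len(non_hub))
        members = np.concatenate(
            [
                rng.choice(hub, size=n_hub, replace=False),
                rng.choice(non_hub, size=n_rest, replace=False),
            ]
        )
        sets.append(GeneSet(name=f"SET{k:03d}", genes=frozenset(members)))
    return sets


def expected_pairwise_jaccard(cfg: SimConfig, size: int | None = None) -> float:
    """Analytic expectation of the Jaccard index between two generated sets
    of the given size (default: the configured median size)."""
    s = float(size if size is not None else cfg.set_size_median)
    h = cfg.hub_fraction * s
    rest = s - h
    n_non_hub = cfg.n_genes - cfg.hub_size
    e_inter = h * h / cfg.hub_size + rest * rest / n_non_hub
    return e_inter / (2.0 * s - e_inter)


def simulate_cnvs(
    cfg: SimConfig,
    genes: pd.DataFrame,
    sets: list[GeneSet],
    rng: np.random.Generator | None = None,
    probes: dict[str, np.ndarray] | None = None,
) -> tuple[pd.DataFrame, TruthRecord]:
    """Draw annotated CNVs per stratum and assign phenotypes generatively.

    Stratum intercepts are calibrated so the *expected* case fraction matches
    each stratum's target; realized case/control totals are random (the
    permutation machinery conditions on the realized counts, as the analysis
    does).
    """
    rng = np.random.default_rng(cfg.seed + 2) if rng is None else rng
    index = GeneIndex(genes)
    chroms = list(cfg.chrom_lengths)
    clens = np.array([cfg.chrom_lengths[c] for c in chroms], dtype=float)
    chrom_p = clens / clens.sum()

    frames = []
    sample_counter = 0
    for spec in cfg.strata:
        n = spec.n_cnv
        states = np.where(
            rng.random(n) < cfg.deletion_fraction, "deletion", "duplication"
        )
        lengths = np.empty(n, dtype=np.int64)
        for state in ("deletion", "duplication"):
            m = states == state
            need = int(m.sum())
            drawn = np.empty(0)
            while len(drawn) < need:
                cand = _lognormal(
                    rng, cfg.cnv_len_median[state], cfg.cnv_len_sigma[state], 2 * need
                )
                drawn = np.concatenate([drawn, cand[cand >= cfg.cnv_min_len]])
            lengths[m] = np.round(drawn[:need]).astype(np.int64)
        which = rng.choice(len(chroms), size=n, p=chrom_p)
        starts = np.empty(n, dtype=np.int64)
        for i in range(n):
            clen = cfg.chrom_lengths[chroms[which[i]]]
            lengths[i] = min(lengths[i], clen - 1)
            starts[i] = rng.integers(0, clen - lengths[i])
        n_probes = np.zeros(n, dtype=np.int64)
        if probes is not None:
            for i in range(n):
                pos = probes[chroms[which[i]]]
                n_probes[i] = np.searchsorted(pos, starts[i] + lengths[i]) - np.searchsorted(
                    pos, starts[i]
                )
        else:
            n_probes = np.maximum((lengths // cfg.probe_spacing), 15)
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": [
                        f"S{(sample_counter + i) // cfg.cnvs_per_sample:06d}"
                        for i in range(n)
                    ],
                    "chrom": [chroms[w] for w in which],
                    "start": starts,
                    "end": starts + lengths,
                    "copy_state": states,
                    "n_probes": n_probes,
                    "study": spec.study,
                    "chip": spec.chip,
                    "phenotype": 0,
                }
            )
        )
        sample_counter += n
    rows = pd.concat(frames, ignore_index=True)
    rows = annotate(rows, index)

    # linear predictor from the embedded model, covariates via real annotation
    lp = cfg.b_size * rows["size_kb"].to_numpy() + cfg.b_total * rows[
        "n_genes_total"
    ].to_numpy(dtype=float)
    by_name = {s.name: s for s in sets}
    for name, beta in cfg.set_effects.items():
        lp = lp + beta * hit_count_column(rows, by_name[name]).astype(float)

    intercepts: dict[str, float] = {}
    strat_key = rows["study"].astype(str) + "|" + rows["chip"].astype(str)
    for spec in cfg.strata:
        key = f"{spec.study}|{spec.chip}"
        mask = (strat_key == key).to_numpy()
        a = float(logit(spec.case_fraction) - lp[mask].mean())
        intercepts[key] = a
        lp[mask] += a

    prob = expit(lp)
    if cfg.per_individual:
        pheno = np.zeros(len(rows), dtype=int)
        for sid, idx in rows.groupby("sample_id").groups.items():
            idx = np.asarray(idx)
            pheno[idx] = int(rng.random() < prob[idx].mean())
    else:
        pheno = (rng.random(len(rows)) < prob).astype(int)
    rows["phenotype"] = pheno

    realized = {}
    for spec in cfg.strata:
        key = f"{spec.study}|{spec.chip}"
        mask = (strat_key == key).to_numpy()
        realized[key] = (int(pheno[mask].sum()), int(mask.sum() - pheno[mask].sum()))

    truth = TruthRecord(
        seed=cfg.seed,
        set_betas=dict(cfg.set_effects),
        stratum_intercepts=intercepts,
        linear_predictor=lp,
        realized_counts=realized,
    )
    return rows, truth


def simulate_dataset(
    cfg: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, list[GeneSet], dict[str, np.ndarray], pd.DataFrame, TruthRecord]:
    """Convenience: genome + sets + CNVs from one config and seed.

    Returns (annotated CNV rows, genes, sets, probe map, LCR regions, truth).
    """
    rng = np.random.default_rng(cfg.seed)
    genes, probes, lcr = generate_genome(cfg, rng)
    sets = generate_gene_sets(cfg, genes, rng)
    rows, truth = simulate_cnvs(cfg, genes, sets, rng, probes=probes)
    return rows, genes, sets, probes, lcr, truth
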