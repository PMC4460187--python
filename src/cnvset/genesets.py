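"""Gene models, gene sets (GMT), and CNV-to-gene annotation.

A gene is "hit" by a CNV when the CNV overlaps any part of its genomic span
(>= 1 bp, half-open coordinates).  Annotation attaches to each QC-passing CNV
the identifiers of the genes it hits; regression covariates (total genes hit,
genes hit within a set) are derived from that annotation, so a CNV spanning
several members of one set still contributes a single row to the model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneSet:
    """A named collection of gene identifiers."""

    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.genes)


def load_gmt(path: str | Path) -> list[GeneSet]:
    """Read gene sets from a GMT file (name, description, members...)."""
    sets: list[GeneSet] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has no members")
            name = fields[0]
            if name in seen:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            seen.add(name)
            members = frozenset(g for g in fields[2:] if g)
            if not members:
                raise ValueError(f"{path}:{lineno}: set {name!r} has no members")
            sets.append(GeneSet(name=name, genes=members))
    return sets


def write_gmt(sets: list[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, "na", *sorted(s.genes)]) + "\n")


class GeneIndex:
    """Per-chromosome arrays of gene spans for fast overlap queries."""

    def __init__(self, genes: pd.DataFrame):
        if genes["gene_id"].duplicated().any():
            raise ValueError("gene_id values must be unique")
        self.genes = genes.reset_index(drop=True)
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, grp in self.genes.groupby("chrom", sort=False):
            self._by_chrom[str(chrom)] = (
                grp["start"].to_numpy(np.int64),
                grp["end"].to_numpy(np.int64),
                grp["gene_id"].to_numpy(object),
            )

    def overlapping(self, chrom: str, start: int, end: int) -> frozenset[str]:
        entry = self._by_chrom.get(str(chrom))
        if entry is None:
            return frozenset()
        gs, ge, gid = entry
        mask = (gs < end) & (ge > start)
        return frozenset(gid[mask])

    @property
    def all_gene_ids(self) -> frozenset[str]:
        return frozenset(self.genes["gene_id"])


def genes_hit_by_cnv(cnv, genes: GeneIndex) -> frozenset[str]:
    """Genes whose span overlaps the CNV span by at least one base."""
    return genes.overlapping(cnv.chrom, cnv.start, cnv.end)


def annotate(calls: pd.DataFrame, genes: GeneIndex | pd.DataFrame) -> pd.DataFrame:
    """Attach size_kb, genes_hit, and n_genes_total to each call.

    CNVs hitting no gene are retained (gene deserts stay in the regression).
    """
    if isinstance(genes, pd.DataFrame):
        genes = GeneIndex(genes)
    calls = calls.reset_index(drop=True).copy()
    hits = [
        genes.overlapping(row.chrom, row.start, row.end)
        for row in calls.itertuples(index=False)
    ]
    calls["size_kb"] = (calls["end"] - calls["start"]) / 1000.0
    calls["genes_hit"] = hits
    calls["n_genes_total"] = [len(h) for h in hits]
    return calls


def set_hit_count(cnv, geneset: GeneSet) -> int:
    """Number of the CNV's hit genes that belong to the set."""
    return len(frozenset(cnv.genes_hit) & geneset.genes)


def hit_count_column(rows: pd.DataFrame, geneset: GeneSet) -> np.ndarray:
    """Vectorized set_hit_count over an annotated CNV table."""
    members = geneset.genes
    return np.fromiter(
        (len(g & members) for g in rows["genes_hit"]), dtype=np.int64, count=len(rows)
    )


def build_union_set(
    results,
    sets: list[GeneSet],
    alpha_adj: float = 0.05,
    name: str | None = None,
    analysis: str = "combined",
) -> GeneSet:
    """Union the member genes of all sets with adjusted p below ``alpha_adj``.

    This is the associated-set construction used as a burden predictor: the
    pooled membership of every annotation surviving multiple-testing
    correction in one analysis.
    """
    by_name = {s.name: s for s in sets}
    passing = [r.set_name for r in results if r.p_adj is not None and r.p_adj < alpha_adj]
    if not passing:
        raise ValueError(
            "no gene set passed the adjusted threshold; supply an explicit set list"
        )
    genes: frozenset[str] = frozenset()
    for nm in passing:
        genes = genes | by_name[nm].genes
    return GeneSet(name=name or f"CNS_SZ_{analysis}", genes=genes)
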