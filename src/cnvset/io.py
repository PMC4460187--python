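"""Readers and writers for the tabular formats the pipeline consumes.

All genomic intervals are held internally as 0-based half-open [start, end).
BED input is taken as-is; the 1-based inclusive TSV dialect (``coords="1based"``)
is converted on read.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

CNV_COLUMNS = [
    "sample_id", "chrom", "start", "end", "copy_state",
    "n_probes", "study", "chip", "phenotype",
]

_STATE_ALIASES = {
    "DEL": "deletion", "DUP": "duplication",
    "deletion": "deletion", "duplication": "duplication",
    "del": "deletion", "dup": "duplication",
}


def _validate_cnv_frame(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CNV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"CNV table missing columns: {missing}")
    df = df.copy()
    df["copy_state"] = df["copy_state"].map(_STATE_ALIASES)
    if df["copy_state"].isna().any():
        raise ValueError("copy_state must be one of DEL/DUP (or deletion/duplication)")
    df["phenotype"] = df["phenotype"].astype(int)
    if not df["phenotype"].isin([0, 1]).all():
        raise ValueError("phenotype must be 1=case or 0=control")
    for col in ("start", "end", "n_probes"):
        df[col] = df[col].astype(np.int64)
    if (df["end"] <= df["start"]).any():
        bad = df.index[df["end"] <= df["start"]][0]
        raise ValueError(f"CNV row {bad}: end must exceed start")
    if (df["n_probes"] < 0).any():
        raise ValueError("n_probes must be nonnegative")
    return df.reset_index(drop=True)


def read_cnv_table(path: str | Path, coords: str = "bed") -> pd.DataFrame:
    """Read a CNV call table (TSV with header).

    ``coords="bed"`` means 0-based half-open as stored; ``coords="1based"``
    means 1-based inclusive start/end, converted here.
    """
    df = pd.read_csv(path, sep="\t")
    if coords == "1based":
        df["start"] = df["start"].astype(np.int64) - 1
    elif coords != "bed":
        raise ValueError(f"unknown coordinate dialect {coords!r}")
    df = _validate_cnv_frame(df)
    if "genes_hit" in df.columns:  # annotated table round-trip
        df["genes_hit"] = [
            frozenset(str(g).split(",")) if isinstance(g, str) and g else frozenset()
            for g in df["genes_hit"]
        ]
        df["n_genes_total"] = [len(g) for g in df["genes_hit"]]
        df["size_kb"] = (df["end"] - df["start"]) / 1000.0
    return df


# PLINK .cnv TYPE field: copy number (0/1 loss, 3/4 gain)
_PLINK_TYPE = {0: "deletion", 1: "deletion", 3: "duplication", 4: "duplication"}


def read_plink_cnv(path: str | Path, sample_info: str | Path) -> pd.DataFrame:
    """Read a PLINK-style .cnv file plus a sample-info sidecar.

    The .cnv file is whitespace-delimited with columns
    FID IID CHR BP1 BP2 TYPE SCORE SITES (1-based inclusive positions).
    The sidecar is a TSV with columns sample_id, study, chip, phenotype.
    """
    cnv = pd.read_csv(path, sep=r"\s+")
    cnv.columns = [c.upper() for c in cnv.columns]
    info = pd.read_csv(sample_info, sep="\t").set_index("sample_id")
    df = pd.DataFrame({
        "sample_id": cnv["IID"].astype(str),
        "chrom": cnv["CHR"].astype(str),
        "start": cnv["BP1"].astype(np.int64) - 1,
        "end": cnv["BP2"].astype(np.int64),
        "copy_state": cnv["TYPE"].astype(int).map(_PLINK_TYPE),
        "n_probes": cnv["SITES"].astype(np.int64),
    })
    for col in ("study", "chip", "phenotype"):
        df[col] = df["sample_id"].map(info[col]).to_numpy()
    if df[["study", "chip", "phenotype"]].isna().any().any():
        missing = df.loc[df["study"].isna(), "sample_id"].unique()[:5]
        raise ValueError(f"samples absent from sidecar: {list(missing)}")
    return _validate_cnv_frame(df)


def read_bed_regions(path: str | Path) -> pd.DataFrame:
    """Read a 3-column BED into a normalized (sorted per chromosome) frame."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        usecols=[0, 1, 2], names=["chrom", "start", "end"],
    )
    return normalize_regions(df)


def normalize_regions(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df["chrom"] = df["chrom"].astype(str)
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    if (df["end"] <= df["start"]).any():
        raise ValueError("region with end <= start")
    return df.sort_values(["chrom", "start", "end"]).reset_index(drop=True)


def read_probe_map(path: str | Path) -> dict[str, np.ndarray]:
    """Read a 2-column TSV (chrom, pos) into sorted per-chromosome arrays."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", names=["chrom", "pos"])
    out: dict[str, np.ndarray] = {}
    for chrom, grp in df.groupby("chrom", sort=True):
        pos = np.sort(grp["pos"].astype(np.int64).to_numpy())
        if len(np.unique(pos)) != len(pos):
            pos = np.unique(pos)
        out[str(chrom)] = pos
    return out


def write_probe_map(probes: dict[str, np.ndarray], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(probes):
            for pos in probes[chrom]:
                fh.write(f"{chrom}\t{int(pos)}\n")


def read_gene_table(path: str | Path) -> pd.DataFrame:
    """Read genes from BED4 (chrom start end gene_id) or a headered TSV."""
    with open(path) as fh:
        first = fh.readline()
    if "gene_id" in first:
        df = pd.read_csv(path, sep="\t")[["gene_id", "chrom", "start", "end"]]
    else:
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            usecols=[0, 1, 2, 3], names=["chrom", "start", "end", "gene_id"],
        )[["gene_id", "chrom", "start", "end"]]
    df["chrom"] = df["chrom"].astype(str)
    df["gene_id"] = df["gene_id"].astype(str)
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    if (df["end"] <= df["start"]).any():
        raise ValueError("gene with end <= start")
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"duplicate gene_id {dup!r}")
    return df.sort_values(["chrom", "start"]).reset_index(drop=True)


def write_gene_bed(genes: pd.DataFrame, path: str | Path) -> None:
    genes[["chrom", "start", "end", "gene_id"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def write_cnv_table(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    if "genes_hit" in out.columns:
        out["genes_hit"] = out["genes_hit"].map(
            lambda g: ",".join(sorted(g)) if isinstance(g, (frozenset, set)) else (g or "")
        )
    out.to_csv(path, sep="\t", index=False)
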