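"""Post-calling CNV quality control.

The QC chain takes raw per-sample CNV calls and produces the analysis-ready
set of large, rare CNVs:

1. fragmented calls from one sample are re-joined when the gap between two
   same-state calls is less than half their combined length;
2. calls mostly (>50%) covered by low-copy repeats are dropped;
3. calls with probe density below 1 probe / 20 kb are dropped;
4. common calls (carrier frequency > 1% under 50% reciprocal-overlap
   clustering within copy-state) are dropped;
5. calls shorter than 100 kb or covered by fewer than 15 probes are dropped.

A separate `remove_known_loci` step supports the sensitivity re-analysis in
which calls overlapping established disease loci are excluded.
"""

from __future__ import annotations

import logging
import warnings
from collections.abc import Iterable

import numpy as np
import pandas as pd

from .io import normalize_regions

log = logging.getLogger(__name__)

DEFAULT_MIN_LEN = 100_000
DEFAULT_MIN_PROBES = 15
DEFAULT_MAX_FREQ = 0.01
DEFAULT_RECIP_OVERLAP = 0.5
DEFAULT_MAX_LCR_OVERLAP = 0.5
DEFAULT_MIN_PROBE_DENSITY = 1.0 / 20_000.0


def _check_sample_metadata(calls: pd.DataFrame) -> None:
    meta = calls.groupby("sample_id")[["study", "chip", "phenotype"]].nunique()
    bad = meta[(meta > 1).any(axis=1)]
    if len(bad):
        raise ValueError(
            f"conflicting study/chip/phenotype within sample(s): {list(bad.index[:5])}"
        )


def merge_adjacent(calls: pd.DataFrame) -> pd.DataFrame:
    """Join same-sample, same-chromosome, same-state calls separated by a gap
    smaller than 50% of their combined length; iterate to a fixpoint.

    Merged spans run min(start)..max(end); probe counts are summed.
    """
    _check_sample_metadata(calls)
    pieces = []
    for _, grp in calls.groupby(["sample_id", "chrom", "copy_state"], sort=False):
        rows = grp.sort_values(["start", "end"]).to_dict("records")
        changed = True
        while changed:
            changed = False
            out = [rows[0]]
            for nxt in rows[1:]:
                cur = out[-1]
                len_cur = cur["end"] - cur["start"]
                len_nxt = nxt["end"] - nxt["start"]
                gap = nxt["start"] - cur["end"]
                if gap < 0.5 * (len_cur + len_nxt):
                    cur = dict(cur)
                    cur["end"] = max(cur["end"], nxt["end"])
                    cur["n_probes"] = cur["n_probes"] + nxt["n_probes"]
                    out[-1] = cur
                    changed = True
                else:
                    out.append(nxt)
            rows = out
        pieces.extend(rows)
    merged = pd.DataFrame(pieces, columns=calls.columns)
    return merged.sort_values(["sample_id", "chrom", "start"]).reset_index(drop=True)


def _merge_intervals(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Collapse sorted intervals into their disjoint union."""
    ms, me = [], []
    for s, e in zip(starts, ends):
        if ms and s <= me[-1]:
            me[-1] = max(me[-1], e)
        else:
            ms.append(s)
            me.append(e)
    return np.asarray(ms), np.asarray(me)


def _coverage_by_union(start: int, end: int, ms: np.ndarray, me: np.ndarray) -> int:
    """Base pairs of [start, end) covered by the disjoint union (ms, me)."""
    if len(ms) == 0:
        return 0
    overlap = np.minimum(end, me) - np.maximum(start, ms)
    return int(np.sum(np.clip(overlap, 0, None)))


def _regions_by_chrom(regions: pd.DataFrame) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    regions = normalize_regions(regions)
    out = {}
    for chrom, grp in regions.groupby("chrom", sort=False):
        out[str(chrom)] = _merge_intervals(
            grp["start"].to_numpy(), grp["end"].to_numpy()
        )
    return out


def filter_lcr(
    calls: pd.DataFrame,
    lcr: pd.DataFrame,
    max_overlap_frac: float = DEFAULT_MAX_LCR_OVERLAP,
) -> pd.DataFrame:
    """Drop calls covered by the union of low-copy-repeat intervals over more
    than ``max_overlap_frac`` of their length (strict inequality)."""
    by_chrom = _regions_by_chrom(lcr)
    keep = np.ones(len(calls), dtype=bool)
    for i, row in enumerate(calls.itertuples(index=False)):
        ms, me = by_chrom.get(str(row.chrom), (np.array([]), np.array([])))
        cov = _coverage_by_union(row.start, row.end, ms, me)
        keep[i] = cov <= max_overlap_frac * (row.end - row.start)
    return calls.loc[keep].reset_index(drop=True)


def filter_probe_density(
    calls: pd.DataFrame,
    probes: dict[str, np.ndarray] | None,
    min_density: float = DEFAULT_MIN_PROBE_DENSITY,
) -> pd.DataFrame:
    """Drop calls whose probe density falls below ``min_density`` (1/20 kb).

    Density is counted from the probe position map (probes p with
    start <= p < end), not from the stored n_probes, which may double-count
    after merging.  If no map is supplied, falls back to n_probes/length with
    a warning.
    """
    if probes is None:
        warnings.warn(
            "no probe map supplied; falling back to stored n_probes for density",
            stacklevel=2,
        )
        counts = calls["n_probes"].to_numpy()
    else:
        missing = set(calls["chrom"].astype(str)) - set(probes)
        if missing:
            raise KeyError(f"chromosome(s) missing from probe map: {sorted(missing)}")
        counts = np.empty(len(calls), dtype=np.int64)
        for i, row in enumerate(calls.itertuples(index=False)):
            pos = probes[str(row.chrom)]
            counts[i] = np.searchsorted(pos, row.end, side="left") - np.searchsorted(
                pos, row.start, side="left"
            )
    length = (calls["end"] - calls["start"]).to_numpy()
    keep = counts / length >= min_density
    return calls.loc[keep].reset_index(drop=True)


def filter_size_probes(
    calls: pd.DataFrame,
    min_len: int = DEFAULT_MIN_LEN,
    min_probes: int = DEFAULT_MIN_PROBES,
) -> pd.DataFrame:
    """Keep calls with length >= min_len and n_probes >= min_probes."""
    length = calls["end"] - calls["start"]
    keep = (length >= min_len) & (calls["n_probes"] >= min_probes)
    return calls.loc[keep].reset_index(drop=True)


def _reciprocal_clusters(grp: pd.DataFrame, recip_overlap: float) -> np.ndarray:
    """Single-linkage cluster labels under >= recip_overlap reciprocal overlap."""
    starts = grp["start"].to_numpy()
    ends = grp["end"].to_numpy()
    order = np.argsort(starts, kind="stable")
    parent = np.arange(len(grp))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for ii in range(len(order)):
        i = order[ii]
        for jj in range(ii + 1, len(order)):
            j = order[jj]
            if starts[j] >= ends[i]:
                break  # sorted by start: no later call overlaps call i
            ov = min(ends[i], ends[j]) - max(starts[i], starts[j])
            if ov >= recip_overlap * (ends[i] - starts[i]) and ov >= recip_overlap * (
                ends[j] - starts[j]
            ):
                parent[find(i)] = find(j)
    return np.array([find(i) for i in range(len(grp))])


def filter_frequency(
    calls: pd.DataFrame,
    n_samples: int,
    max_freq: float = DEFAULT_MAX_FREQ,
    recip_overlap: float = DEFAULT_RECIP_OVERLAP,
) -> pd.DataFrame:
    """Drop clusters of equivalent calls carried by more than ``max_freq`` of
    all genotyped samples.

    Calls of the same copy-state are clustered by single-linkage at
    >= ``recip_overlap`` reciprocal overlap; a cluster's frequency is its
    number of distinct carrier samples divided by ``n_samples``.
    """
    calls = calls.reset_index(drop=True)
    n_distinct = calls["sample_id"].nunique()
    if n_samples < n_distinct:
        raise ValueError(
            f"n_samples={n_samples} < {n_distinct} distinct sample_ids in the calls"
        )
    keep = np.ones(len(calls), dtype=bool)
    for _, grp in calls.groupby(["chrom", "copy_state"], sort=False):
        labels = _reciprocal_clusters(grp, recip_overlap)
        samples = grp["sample_id"].to_numpy()
        for lab in np.unique(labels):
            mask = labels == lab
            freq = len(set(samples[mask])) / n_samples
            if freq > max_freq:
                keep[grp.index[mask]] = False
    return calls.loc[keep].reset_index(drop=True)


def remove_known_loci(calls: pd.DataFrame, loci: pd.DataFrame) -> pd.DataFrame:
    """Drop calls overlapping any known locus by >= 1 bp (half-open spans)."""
    by_chrom = _regions_by_chrom(loci)
    keep = np.ones(len(calls), dtype=bool)
    for i, row in enumerate(calls.itertuples(index=False)):
        ms, me = by_chrom.get(str(row.chrom), (np.array([]), np.array([])))
        keep[i] = _coverage_by_union(row.start, row.end, ms, me) == 0
    return calls.loc[keep].reset_index(drop=True)


def apply_sample_filter(calls: pd.DataFrame, passing_samples: Iterable[str]) -> pd.DataFrame:
    """Keep calls from samples on an externally supplied pass list.

    Hook for upstream sample-level QC (e.g. intensity-based outlier removal)
    that cannot be recomputed from call tables alone.
    """
    passing = set(passing_samples)
    return calls.loc[calls["sample_id"].isin(passing)].reset_index(drop=True)


def run_qc(
    calls: pd.DataFrame,
    *,
    n_samples: int,
    lcr: pd.DataFrame | None = None,
    probes: dict[str, np.ndarray] | None = None,
    min_len: int = DEFAULT_MIN_LEN,
    min_probes: int = DEFAULT_MIN_PROBES,
    max_freq: float = DEFAULT_MAX_FREQ,
    recip_overlap: float = DEFAULT_RECIP_OVERLAP,
    max_lcr_overlap: float = DEFAULT_MAX_LCR_OVERLAP,
    min_probe_density: float = DEFAULT_MIN_PROBE_DENSITY,
    passing_samples: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Full QC chain: merge, LCR, probe density, frequency, size/probes."""
    if passing_samples is not None:
        calls = apply_sample_filter(calls, passing_samples)
    calls = merge_adjacent(calls)
    if lcr is not None and len(lcr):
        calls = filter_lcr(calls, lcr, max_lcr_overlap)
    calls = filter_probe_density(calls, probes, min_probe_density)
    calls = filter_frequency(calls, n_samples, max_freq, recip_overlap)
    calls = filter_size_probes(calls, min_len, min_probes)
    log.info("QC retained %d calls", len(calls))
    return calls
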