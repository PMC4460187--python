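"""CNV quality-control rules, each checked against a naive oracle."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cnvset.qc import (
    filter_frequency,
    filter_lcr,
    filter_probe_density,
    filter_size_probes,
    merge_adjacent,
    remove_known_loci,
)

from .conftest import calls_frame, make_call

# ---------------------------------------------------------------- merging


def _merge_oracle_all_orders(spans: list[tuple[int, int]]) -> set[tuple[int, int]]:
    """Exhaustive fixpoint: try every merge order; assert they agree."""

    def step(state: frozenset[tuple[int, int]]) -> set[frozenset]:
        out = set()
        items = sorted(state)
        for a, b in itertools.combinations(items, 2):
            (s1, e1), (s2, e2) = sorted([a, b])
            gap = s2 - e1
            if gap < 0.5 * ((e1 - s1) + (e2 - s2)):
                merged = (min(s1, s2), max(e1, e2))
                out.add(state - {a, b} | {merged})
        return out

    results = set()
    frontier = {frozenset(spans)}
    while frontier:
        nxt = set()
        for state in frontier:
            succ = step(state)
            if not succ:
                results.add(state)
            else:
                nxt.update(succ)
        frontier = nxt
    assert len(results) == 1, "merge fixpoint depends on order"
    return set(results.pop())


def _spans(df: pd.DataFrame) -> set[tuple[int, int]]:
    return set(zip(df["start"].astype(int), df["end"].astype(int)))


def test_merge_rule_examples():
    """Gap < half the combined length joins; at or above it does not."""
    single = calls_frame([make_call()])
    assert _spans(merge_adjacent(single)) == {(1_000_000, 1_100_000)}

    pair = calls_frame([
        make_call(start=1_000_000, end=1_100_000, n_probes=30),
        make_call(start=1_160_000, end=1_200_000, n_probes=12),
    ])
    merged = merge_adjacent(pair)  # gap 60 kb < 70 kb
    assert _spans(merged) == {(1_000_000, 1_200_000)}
    assert merged["n_probes"].iloc[0] == 42

    apart = calls_frame([
        make_call(start=1_000_000, end=1_100_000),
        make_call(start=1_180_000, end=1_220_000),
    ])
    assert len(merge_adjacent(apart)) == 2  # gap 80 kb >= 70 kb


def test_merge_cascade_matches_exhaustive_oracle():
    """Merging two calls can bring a third within range; the scan iterates
    to the same fixpoint as exhaustive pairwise merging in every order."""
    spans = [(0, 100_000), (160_000, 260_000), (380_000, 420_000)]
    # first two merge (gap 60k < 100k); span (0, 260k) then reaches the third
    # (gap 120k < 0.5*(260k+40k)=150k) though the middle call alone did not
    # (gap 120k >= 0.5*(100k+40k)=70k ... actually 120k >= 70k: no pair merge)
    calls = calls_frame([make_call(start=s, end=e) for s, e in spans])
    got = _spans(merge_adjacent(calls))
    assert got == _merge_oracle_all_orders(spans) == {(0, 420_000)}


@given(
    st.lists(
        st.tuples(st.integers(0, 40), st.integers(1, 15)).map(
            lambda t: (t[0] * 10_000, t[0] * 10_000 + t[1] * 10_000)
        ),
        min_size=1,
        max_size=5,
    )
)
def test_merge_matches_oracle_and_is_idempotent(spans):
    calls = calls_frame([make_call(start=s, end=e) for s, e in spans])
    once = merge_adjacent(calls)
    assert _spans(once) == _merge_oracle_all_orders(spans)
    assert _spans(merge_adjacent(once)) == _spans(once)


def test_merge_groups_by_sample_chrom_state():
    calls = calls_frame([
        make_call(sample_id="a", start=0, end=100_000),
        make_call(sample_id="b", start=110_000, end=210_000),          # other sample
        make_call(sample_id="a", start=110_000, end=210_000, copy_state="duplication"),
    ])
    assert len(merge_adjacent(calls)) == 3


def test_merge_rejects_conflicting_sample_metadata():
    calls = calls_frame([
        make_call(phenotype=1),
        make_call(start=5_000_000, end=5_200_000, phenotype=0),
    ])
    with pytest.raises(ValueError, match="conflicting"):
        merge_adjacent(calls)


# ---------------------------------------------------------------- LCR filter


def _lcr_coverage_oracle(call, regions, unit=1000):
    """Per-base (scaled) counting of the covered fraction."""
    covered = set()
    for _, s, e in regions.itertuples(index=False):
        covered.update(range(max(call["start"], s) // unit, min(call["end"], e) // unit))
    covered = {b for b in covered if call["start"] // unit <= b < call["end"] // unit}
    return len(covered) * unit / (call["end"] - call["start"])


@pytest.mark.parametrize(
    "lcr_spans,expect_kept",
    [
        ([(1_020_000, 1_080_000)], 0),                       # 60% covered -> removed
        ([(1_000_000, 1_050_000)], 1),                       # exactly 50% -> retained
        ([(1_000_000, 1_030_000), (1_050_000, 1_080_000)], 0),  # union 60% -> removed
    ],
)
def test_filter_lcr_union_coverage(lcr_spans, expect_kept):
    call = make_call(start=1_000_000, end=1_100_000)
    lcr = pd.DataFrame(lcr_spans, columns=["start", "end"]).assign(chrom="chr1")
    kept = filter_lcr(calls_frame([call]), lcr[["chrom", "start", "end"]])
    assert len(kept) == expect_kept
    frac = _lcr_coverage_oracle(call, lcr[["chrom", "start", "end"]])
    assert (frac > 0.5) == (expect_kept == 0)


def test_filter_lcr_invariant_to_region_order():
    rng = np.random.default_rng(0)
    calls = calls_frame(
        [make_call(sample_id=f"s{i}", start=int(s), end=int(s) + 100_000, phenotype=i % 2)
         for i, s in enumerate(rng.integers(0, 5_000_000, 12))]
    )
    spans = [(int(s), int(s) + 60_000) for s in rng.integers(0, 5_000_000, 8)]
    lcr = pd.DataFrame(spans, columns=["start", "end"]).assign(chrom="chr1")
    a = filter_lcr(calls, lcr[["chrom", "start", "end"]])
    b = filter_lcr(calls, lcr.iloc[::-1][["chrom", "start", "end"]])
    pd.testing.assert_frame_equal(a, b)


# ------------------------------------------------------------ probe density


def test_filter_probe_density_boundary_and_oracle():
    """Removed iff mapped-probe density < 1/20 kb; the stored n_probes field
    is ignored when a probe map is available."""
    probes = {"chr1": np.arange(1_000_000, 1_200_000, 20_000)}  # 10 in 200 kb
    at_boundary = calls_frame([make_call(start=1_000_000, end=1_200_000, n_probes=1)])
    assert len(filter_probe_density(at_boundary, probes)) == 1  # exactly 1/20 kb

    probes9 = {"chr1": np.arange(1_000_000, 1_180_000, 20_000)}  # 9 in 200 kb
    assert len(filter_probe_density(at_boundary, probes9)) == 0

    rng = np.random.default_rng(3)
    pos = np.sort(rng.integers(0, 2_000_000, 150))
    probes_r = {"chr1": pos}
    calls = calls_frame(
        [make_call(sample_id=f"s{i}", start=int(s), end=int(s) + 150_000)
         for i, s in enumerate(rng.integers(0, 1_800_000, 20))]
    )
    kept = filter_probe_density(calls, probes_r)
    linear = [
        sum(1 for p in pos if row.start <= p < row.end) / (row.end - row.start)
        >= 1 / 20_000
        for row in calls.itertuples(index=False)
    ]
    assert len(kept) == sum(linear)


def test_filter_probe_density_missing_chrom_errors():
    calls = calls_frame([make_call(chrom="chrX")])
    with pytest.raises(KeyError, match="chrX"):
        filter_probe_density(calls, {"chr1": np.array([5])})


def test_filter_probe_density_fallback_warns():
    calls = calls_frame([make_call(n_probes=20)])
    with pytest.warns(UserWarning, match="probe map"):
        kept = filter_probe_density(calls, None)
    assert len(kept) == 1


# ----------------------------------------------------------- size & probes


@pytest.mark.parametrize(
    "length,n_probes,kept",
    [(100_000, 15, True), (99_999, 40, False), (500_000, 14, False)],
)
def test_filter_size_probes_boundaries(length, n_probes, kept):
    calls = calls_frame([make_call(start=0, end=length, n_probes=n_probes)])
    assert len(filter_size_probes(calls)) == (1 if kept else 0)


# ---------------------------------------------------------------- frequency


def _freq_oracle_clusters(df, recip=0.5):
    """All-pairs transitive closure under reciprocal overlap."""
    n = len(df)
    adj = {i: {i} for i in range(n)}
    rows = df.to_dict("records")
    for i, j in itertools.combinations(range(n), 2):
        a, b = rows[i], rows[j]
        if a["chrom"] != b["chrom"] or a["copy_state"] != b["copy_state"]:
            continue
        ov = min(a["end"], b["end"]) - max(a["start"], b["start"])
        if ov >= recip * (a["end"] - a["start"]) and ov >= recip * (b["end"] - b["start"]):
            adj[i].add(j)
            adj[j].add(i)
    seen, clusters = set(), []
    for i in range(n):
        if i in seen:
            continue
        stack, comp = [i], set()
        while stack:
            k = stack.pop()
            if k in comp:
                continue
            comp.add(k)
            stack.extend(adj[k] - comp)
        seen |= comp
        clusters.append(comp)
    return clusters


def test_filter_frequency_unique_call_kept():
    calls = calls_frame([make_call()])
    assert len(filter_frequency(calls, n_samples=10_000)) == 1


def test_filter_frequency_common_cluster_removed():
    calls = calls_frame(
        [make_call(sample_id=f"s{i}", start=1_000_000 + 1_000 * i,
                   end=1_100_000 + 1_000 * i) for i in range(12)]
    )
    assert len(filter_frequency(calls, n_samples=1_000)) == 0   # 1.2% > 1%
    assert len(filter_frequency(calls, n_samples=2_000)) == 12  # 0.6% <= 1%


def test_filter_frequency_matches_all_pairs_oracle():
    rng = np.random.default_rng(11)
    recs = []
    for i in range(40):
        s = int(rng.integers(0, 600_000))
        ln = int(rng.integers(80_000, 250_000))
        recs.append(
            make_call(sample_id=f"s{i % 30}", start=s, end=s + ln,
                      copy_state=("deletion", "duplication")[int(rng.integers(2))],
                      phenotype=i % 2)
        )
    calls = calls_frame(recs)
    n_samples = 1000
    clusters = _freq_oracle_clusters(calls)
    keep_oracle = np.ones(len(calls), dtype=bool)
    for comp in clusters:
        carriers = {calls["sample_id"].iloc[k] for k in comp}
        if len(carriers) / n_samples > 0.01:
            for k in comp:
                keep_oracle[k] = False
    got = filter_frequency(calls, n_samples=n_samples, max_freq=0.01)
    expect = calls.loc[keep_oracle].reset_index(drop=True)
    pd.testing.assert_frame_equal(got, expect)


def test_filter_frequency_rejects_bad_n_samples():
    calls = calls_frame([make_call(sample_id="a"), make_call(sample_id="b", start=5e6, end=5.1e6)])
    with pytest.raises(ValueError, match="n_samples"):
        filter_frequency(calls, n_samples=1)


# --------------------------------------------------------------- known loci


def test_remove_known_loci_any_overlap_halfopen():
    loci = pd.DataFrame({"chrom": ["chr1"], "start": [1_100_000 - 1], "end": [1_300_000]})
    touching = calls_frame([make_call()])          # overlaps by exactly 1 bp
    assert len(remove_known_loci(touching, loci)) == 0
    abutting = calls_frame([make_call(end=1_100_000 - 1)])  # call.end == locus.start
    assert len(remove_known_loci(abutting, loci)) == 1


def test_remove_known_loci_matches_naive_scan():
    rng = np.random.default_rng(5)
    calls = calls_frame(
        [make_call(sample_id=f"s{i}", start=int(s), end=int(s) + 120_000, phenotype=i % 2)
         for i, s in enumerate(rng.integers(0, 8_000_000, 30))]
    )
    loci = pd.DataFrame(
        {"chrom": "chr1", "start": (sp := rng.integers(0, 8_000_000, 6)), "end": sp + 400_000}
    )
    kept = remove_known_loci(calls, loci)
    naive = [
        not any(row.start < e and row.end > s for s, e in zip(loci["start"], loci["end"]))
        for row in calls.itertuples(index=False)
    ]
    assert len(kept) == sum(naive)


# ---------------------------------------------------------------- chain laws


def test_filters_are_idempotent_subsequences(small_world):
    calls = small_world["rows"][
        ["sample_id", "chrom", "start", "end", "copy_state", "n_probes",
         "study", "chip", "phenotype"]
    ]
    probes = small_world["probes"]
    lcr = small_world["lcr"]
    for f in (
        lambda c: filter_lcr(c, lcr),
        lambda c: filter_probe_density(c, probes),
        lambda c: filter_size_probes(c),
        lambda c: filter_frequency(c, n_samples=20_000),
        lambda c: remove_known_loci(c, lcr),
    ):
        out = f(calls)
        assert len(out) <= len(calls)
        # subsequence of the input rows
        merged = calls.merge(out, how="inner")
        assert len(merged) == len(out)
        pd.testing.assert_frame_equal(f(out), out)  # idempotent


def test_clean_fixture_passes_chain_unchanged():
    probes = {"chr1": np.arange(0, 10_000_000, 10_000)}
    calls = calls_frame(
        [make_call(sample_id=f"s{i}", start=i * 1_000_000, end=i * 1_000_000 + 200_000,
                   n_probes=20, phenotype=i % 2) for i in range(5)]
    )
    out = merge_adjacent(calls)
    out = filter_probe_density(out, probes)
    out = filter_frequency(out, n_samples=10_000)
    out = filter_size_probes(out)
    pd.testing.assert_frame_equal(
        out.sort_values("start").reset_index(drop=True),
        calls.sort_values("start").reset_index(drop=True),
    )
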