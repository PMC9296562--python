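"""Export detection and size partitioning: hand oracles and set properties."""

import numpy as np
import pytest

from particle_export import (
    MissingSamplesError,
    annotate_dataset,
    deployment_consistency,
    detect_export,
    partition_by_size,
    pool_presence,
)

from conftest import PHYTO_LINEAGES, make_dataset

SW = {"sample_type": "seawater"}
BULK = {"sample_type": "bulk_trap"}
PART = {"sample_type": "particle", "particle_class": "aggregate", "delay_days": 0.0}


def phyto_lineages(asvs):
    return {a: PHYTO_LINEAGES["diatom"] for a in asvs}


def test_pool_presence_is_union_over_samples():
    ds = make_dataset(
        {"p1": {"a": 2, "b": 0}, "p2": {"a": 0, "b": 0}},
        meta={"p1": PART, "p2": PART},
    )
    assert pool_presence(ds, "particle", 1) == {"a"}


def test_pool_presence_threshold_on_pooled_sum():
    # pooled reads of a = 1 + 1 = 2 < 3: excluded
    ds = make_dataset(
        {"p1": {"a": 1}, "p2": {"a": 1}},
        meta={"p1": PART, "p2": PART},
    )
    assert pool_presence(ds, "particle", 1, min_reads_per_asv=3) == set()
    assert pool_presence(ds, "particle", 1, min_reads_per_asv=2) == {"a"}


def test_pool_presence_no_samples_errors():
    ds = make_dataset({"s1": {"a": 1}})
    with pytest.raises(MissingSamplesError):
        pool_presence(ds, "particle", 1)


def hand_export_dataset(trap_detects):
    """Surface group reads a:30 b:10 c:60; the trap sample carries `trap_detects`."""
    ds = make_dataset(
        {
            "sw": {"a": 30, "b": 10, "c": 60},
            "trap": {x: (5 if x in trap_detects else 0) for x in "abc"},
        },
        meta={"sw": SW, "trap": BULK},
        lineages=phyto_lineages("abc"),
    )
    return ds, annotate_dataset(ds)


def test_detect_export_hand_arithmetic():
    ds, ann = hand_export_dataset({"a", "c"})
    part = detect_export(ds, ann, 1)
    g = part.groups["Bacillariophyta"]
    assert g.exported_asvs == {"a", "c"}
    assert g.exported_asv_fraction == pytest.approx(2 / 3)
    assert g.exported_read_share == pytest.approx(0.90)


@pytest.mark.parametrize("detected, frac, share", [(set(), 0.0, 0.0), ({"a", "b", "c"}, 1.0, 1.0)])
def test_detect_export_empty_and_full_intersection(detected, frac, share):
    ds, ann = hand_export_dataset(detected)
    g = detect_export(ds, ann, 1).groups["Bacillariophyta"]
    assert g.exported_asv_fraction == frac
    assert g.exported_read_share == pytest.approx(share, abs=1e-12)


def test_heterotrophs_never_enter_export_detection():
    ds = make_dataset(
        {"sw": {"h": 50, "a": 50}, "trap": {"h": 5, "a": 5}},
        meta={"sw": SW, "trap": BULK},
        lineages={"h": PHYTO_LINEAGES["opistho"], "a": PHYTO_LINEAGES["diatom"]},
    )
    part = detect_export(ds, annotate_dataset(ds), 1)
    assert "Opisthokonta" not in part.groups
    assert part.groups["Bacillariophyta"].exported_asvs == {"a"}


def test_partition_by_size_hand_set_algebra():
    ds = make_dataset(
        {
            "bulk": {"x": 1, "y": 1, "z": 1, "q": 0},
            "p1": {"y": 3, "q": 2, "x": 0, "z": 0},
        },
        meta={"bulk": BULK, "p1": PART},
        lineages=phyto_lineages("xyzq"),
    )
    part = partition_by_size(ds, annotate_dataset(ds), 1)
    g = part.groups["Bacillariophyta"]
    assert g.large_particle_asvs == {"y"}
    assert g.small_only_asvs == {"x", "z"}
    assert g.large_fraction == pytest.approx(1 / 3)
    assert g.particle_only_asvs == {"q"}


@pytest.mark.parametrize(
    "particle_counts, expected",
    [({"x": 1, "y": 1, "z": 1}, 1.0), ({"q": 1}, 0.0)],
)
def test_partition_extremes(particle_counts, expected):
    ds = make_dataset(
        {"bulk": {"x": 1, "y": 1, "z": 1}, "p1": particle_counts},
        meta={"bulk": BULK, "p1": PART},
        lineages=phyto_lineages("xyzq"),
    )
    g = partition_by_size(ds, annotate_dataset(ds), 1).groups["Bacillariophyta"]
    assert g.large_fraction == expected


def test_partition_requires_bulk_samples(paperlike_annotated):
    ds, _, ann = paperlike_annotated
    with pytest.raises(MissingSamplesError, match="no bulk"):
        partition_by_size(ds, ann, 1)


def test_deployment_consistency_identical_and_hand_delta():
    # deployment A traps {a, b}; deployment B misses b, which carries 5% of reads
    ds = make_dataset(
        {
            "sw": {"a": 95, "b": 5},
            "tA": {"a": 2, "b": 2},
            "tB": {"a": 2, "b": 0},
        },
        meta={
            "sw": SW,
            "tA": {**BULK, "deployment_id": "A"},
            "tB": {**BULK, "deployment_id": "B"},
        },
        lineages=phyto_lineages("ab"),
    )
    ann = annotate_dataset(ds)
    table = deployment_consistency(ds, ann, 1, deployment_ids=("A", "B"))
    row = table[table["group"] == "Bacillariophyta"].iloc[0]
    assert row["abs_delta"] == pytest.approx(0.05)
    # identical deployments: zero delta
    same = deployment_consistency(ds, ann, 1, deployment_ids=("A", "A"))
    assert same.attrs["max_delta"] == 0.0


def test_deployment_consistency_matches_bruteforce_recompute():
    rng = np.random.default_rng(5)
    for _ in range(20):
        n_asv = rng.integers(3, 8)
        asvs = [f"a{i}" for i in range(n_asv)]
        counts = {"sw": {a: int(rng.integers(1, 50)) for a in asvs}}
        meta = {"sw": SW}
        for dep in "AB":
            counts[f"t{dep}"] = {a: int(rng.integers(0, 2)) for a in asvs}
            meta[f"t{dep}"] = {**BULK, "deployment_id": dep}
        ds = make_dataset(counts, meta=meta, lineages=phyto_lineages(asvs))
        ann = annotate_dataset(ds)
        table = deployment_consistency(ds, ann, 1, deployment_ids=("A", "B"))
        total = sum(counts["sw"].values())
        shares = []
        for dep in "AB":
            detected = {a for a in asvs if counts[f"t{dep}"][a] >= 1}
            shares.append(sum(counts["sw"][a] for a in detected) / total)
        expected = abs(shares[0] - shares[1])
        got = table[table["group"] == "Bacillariophyta"]["abs_delta"].iloc[0]
        assert got == pytest.approx(expected, abs=1e-12)


def test_exported_sets_match_bruteforce_on_random_instances():
    """Set semantics against exhaustive enumeration, <=10 ASVs."""
    rng = np.random.default_rng(11)
    for _ in range(200):
        n_asv = int(rng.integers(2, 11))
        asvs = [f"a{i}" for i in range(n_asv)]
        sw = {a: int(rng.integers(0, 40)) for a in asvs}
        bulk = {a: int(rng.integers(0, 3)) for a in asvs}
        part_counts = {a: int(rng.integers(0, 3)) for a in asvs}
        if sum(sw.values()) == 0:
            sw[asvs[0]] = 1
        ds = make_dataset(
            {"sw": sw, "bulk": bulk, "p1": part_counts},
            meta={"sw": SW, "bulk": BULK, "p1": PART},
            lineages=phyto_lineages(asvs),
        )
        ann = annotate_dataset(ds)
        surface = {a for a in asvs if sw[a] >= 1}
        trap = {a for a in asvs if bulk[a] >= 1 or part_counts[a] >= 1}
        part = detect_export(ds, ann, 1)
        got_exported = set().union(*(g.exported_asvs for g in part.groups.values()))
        assert got_exported == surface & trap
        sp = partition_by_size(ds, ann, 1)
        bulk_set = {a for a in asvs if bulk[a] >= 1}
        particle_set = {a for a in asvs if part_counts[a] >= 1}
        got_large = set().union(*(g.large_particle_asvs for g in sp.groups.values()))
        got_small = set().union(*(g.small_only_asvs for g in sp.groups.values()))
        assert got_large == bulk_set & particle_set
        assert got_small == bulk_set - particle_set


def test_adding_trap_samples_only_grows_export():
    """Monotonicity: exported sets/fractions non-decreasing in trap samples."""
    rng = np.random.default_rng(3)
    asvs = [f"a{i}" for i in range(8)]
    sw = {a: int(rng.integers(1, 30)) for a in asvs}
    counts = {"sw": sw}
    meta = {"sw": SW}
    for i in range(5):
        counts[f"p{i}"] = {a: int(rng.integers(0, 2)) for a in asvs}
        meta[f"p{i}"] = PART
    ds_full = make_dataset(counts, meta=meta, lineages=phyto_lineages(asvs))
    ann = annotate_dataset(ds_full)
    prev_sets: set = set()
    prev_share = 0.0
    for k in range(1, 6):
        keep = ["sw"] + [f"p{i}" for i in range(k)]
        part = detect_export(ds_full.subset_samples(keep), ann, 1)
        g = part.groups["Bacillariophyta"]
        assert prev_sets <= g.exported_asvs
        assert g.exported_read_share >= prev_share - 1e-12
        prev_sets, prev_share = g.exported_asvs, g.exported_read_share


def test_surface_read_shares_sum_to_one(paperlike_annotated):
    ds, _, ann = paperlike_annotated
    part = detect_export(ds, ann, 3)
    for g in part.groups.values():
        assert sum(g.surface_read_share.values()) == pytest.approx(1.0, abs=1e-12)
        assert g.exported_read_share == pytest.approx(
            sum(g.surface_read_share[a] for a in g.exported_asvs), abs=1e-12
        )
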