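"""Presence/absence richness, percent loss and particle-class contrasts."""

import math

import numpy as np
import pandas as pd
import pytest

from particle_export import (
    annotate_dataset,
    genus_contrast,
    one_way_anova,
    percent_loss,
    presence_absence,
    richness_by,
    welch_t,
)

from conftest import PHYTO_LINEAGES, make_dataset

PART0 = {"sample_type": "particle", "particle_class": "aggregate", "delay_days": 0.0, "deployment_id": "D1"}
PART2 = {"sample_type": "particle", "particle_class": "aggregate", "delay_days": 2.0, "deployment_id": "D1"}


def test_presence_absence_threshold_boundaries():
    ds = make_dataset(
        {"s1": {"a": 4, "b": 5, "c": 1}, "s2": {"a": 5, "b": 5, "c": 0}}
    )
    pa = presence_absence(ds, min_total=10)
    # a totals 9: removed; b totals 10: retained
    assert "a" not in pa.columns and "b" in pa.columns
    assert pa.loc["s1", "b"] == 1 and pa.loc["s2", "c" if "c" in pa.columns else "b"] in (0, 1)


def test_presence_absence_hand_transform():
    ds = make_dataset(
        {"s1": {"a": 7, "b": 0, "c": 12}, "s2": {"a": 3, "b": 11, "c": 0}, "s3": {"a": 0, "b": 2, "c": 1}}
    )
    pa = presence_absence(ds, min_total=10)
    expected = pd.DataFrame(
        {"a": [1, 1, 0], "b": [0, 1, 1], "c": [1, 0, 1]},
        index=["s1", "s2", "s3"],
    )
    pd.testing.assert_frame_equal(pa.astype(int), expected, check_names=False)


def test_presence_absence_idempotent_and_monotone():
    rng = np.random.default_rng(1)
    ds = make_dataset(
        {f"s{i}": {f"a{j}": int(rng.integers(0, 8)) for j in range(10)} for i in range(4)}
    )
    pa5 = presence_absence(ds, min_total=5)
    pa9 = presence_absence(ds, min_total=9)
    assert set(pa9.columns) <= set(pa5.columns)
    # idempotence: binarising a binary table at threshold 1 changes nothing
    ds_bin = make_dataset({s: pa5.loc[s].to_dict() for s in pa5.index})
    pd.testing.assert_frame_equal(
        presence_absence(ds_bin, min_total=1).astype(int), pa5.astype(int)
    )


def richness_toy():
    lineages = {
        "d1": PHYTO_LINEAGES["dino"], "d2": PHYTO_LINEAGES["dino"],
        "c1": PHYTO_LINEAGES["chloro"], "h1": PHYTO_LINEAGES["opistho"],
    }
    counts = {
        "p1": {"d1": 5, "d2": 5, "c1": 5, "h1": 5},
        "p2": {"d1": 5, "d2": 5, "c1": 5, "h1": 0},
        "q1": {"d1": 0, "d2": 5, "c1": 5, "h1": 5},  # delayed
        "q2": {"d1": 0, "d2": 0, "c1": 5, "h1": 5},  # delayed
    }
    meta = {"p1": PART0, "p2": PART0, "q1": PART2, "q2": PART2}
    ds = make_dataset(counts, meta=meta, lineages=lineages)
    return ds, annotate_dataset(ds)


def test_richness_counts_match_hand_tally():
    ds, ann = richness_toy()
    pa = presence_absence(ds, min_total=1)
    rec = richness_by(pa, ds, ann, group_key="trophic_mode")
    lut = rec.set_index(["sample_id", "group"])["richness"]
    assert lut[("p1", "phytoplankton")] == 3
    assert lut[("p2", "heterotroph")] == 0
    assert lut[("q2", "phytoplankton")] == 1
    by_genus = richness_by(pa, ds, ann, group_key="genus")
    glut = by_genus.set_index(["sample_id", "group"])["richness"]
    assert glut[("p1", "Gyrodinium")] == 2
    assert glut[("q1", "Gyrodinium")] == 1


def test_percent_loss_arithmetic_and_signs():
    rec = pd.DataFrame(
        {
            "sample_id": ["b1", "b2", "x1", "x2", "x3"],
            "particle_class": ["aggregate"] * 5,
            "delay_days": [0.0, 0.0, 2.0, 2.0, 2.0],
            "deployment_id": ["D1"] * 5,
            "group": ["dino"] * 5,
            "richness": [12, 8, 2, 10, 14],  # baseline mean 10
        }
    )
    summary = percent_loss(rec)
    row = summary.iloc[0]
    # per-particle losses: 80%, 0%, -40% (negative allowed)
    per = summary.attrs["per_particle"]["percent_loss"].tolist()
    assert per == pytest.approx([80.0, 0.0, -40.0])
    assert row["mean_percent_loss"] == pytest.approx(np.mean([80, 0, -40]))
    assert row["sd_percent_loss"] == pytest.approx(np.std([80, 0, -40], ddof=1))
    assert row["n"] == 3


def test_percent_loss_zero_baseline_errors():
    rec = pd.DataFrame(
        {
            "sample_id": ["b1", "b2", "x1", "x2"],
            "particle_class": ["aggregate"] * 4,
            "delay_days": [0.0, 0.0, 2.0, 2.0],
            "deployment_id": ["D1"] * 4,
            "group": ["g"] * 4,
            "richness": [0, 0, 1, 2],
        }
    )
    with pytest.raises(ZeroDivisionError):
        percent_loss(rec)


# -- Welch t and ANOVA against independent closed forms ----------------


def welch_closed_form(a, b):
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    from scipy.stats import t as tdist

    p = 2 * tdist.sf(abs(t), df)
    return t, df, p


def test_welch_identical_groups():
    res = welch_t([1, 2, 3], [1, 2, 3])
    assert res.t == 0.0 and res.p == 1.0


def test_welch_matches_hand_computation():
    a, b = [3.1, 4.5, 2.2, 5.0], [7.7, 8.1, 9.4]
    res = welch_t(a, b)
    t, df, p = welch_closed_form(a, b)
    assert res.t == pytest.approx(t, abs=1e-10)
    assert res.df == pytest.approx(df, abs=1e-10)
    assert res.p == pytest.approx(p, abs=1e-10)


def test_welch_shifted_groups_significant_with_fixed_sign():
    a, b = [11, 12, 13], [1, 2, 3]
    res = welch_t(a, b)
    assert res.t > 0  # mean(a) > mean(b)
    assert res.p < 0.01


def anova_closed_form(groups):
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    ssb = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
    ssw = sum(((np.asarray(g) - np.mean(g)) ** 2).sum() for g in groups)
    dfb, dfw = len(groups) - 1, len(all_vals) - len(groups)
    f = (ssb / dfb) / (ssw / dfw)
    from scipy.stats import f as fdist

    return f, 2 * 0 + fdist.sf(f, dfb, dfw)


def test_anova_matches_closed_form_and_detects_separation():
    groups = [[0.9, 1.1, 1.0], [4.8, 5.2, 5.0], [8.9, 9.1, 9.0]]
    res = one_way_anova(groups)
    f, p = anova_closed_form(groups)
    assert res.f == pytest.approx(f, rel=1e-10)
    assert res.p == pytest.approx(p, rel=1e-10)
    assert res.p < 0.05


def test_anova_identical_constant_groups_boundary():
    res = one_way_anova([[2, 2, 2], [2, 2, 2]])
    assert res.f == 0.0 and res.p == 1.0


def test_anova_null_rejection_rate_near_alpha():
    rng = np.random.default_rng(9)
    rejections = 0
    n = 300
    for _ in range(n):
        groups = [rng.normal(size=5) for _ in range(3)]
        rejections += one_way_anova(groups).p < 0.05
    rate = rejections / n
    se = math.sqrt(0.05 * 0.95 / n)
    assert abs(rate - 0.05) <= 3 * se


# -- genus contrast ----------------------------------------------------


def contrast_dataset(spike: bool):
    lineages = {
        "g1": PHYTO_LINEAGES["chloro"],
        "g2": PHYTO_LINEAGES["dino"],
        "bg": PHYTO_LINEAGES["opistho"],
    }
    counts, meta = {}, {}
    rng = np.random.default_rng(0)
    for i in range(5):
        # the spiked genus moves with tiny variance; other genera carry
        # enough count noise that the compositional closure effect of the
        # spike stays far from the strict alpha
        g1 = (60 if spike else 40) + int(rng.integers(0, 3))
        counts[f"llp{i}"] = {
            "g1": g1,
            "g2": 40 + int(rng.integers(0, 25)),
            "bg": 920 + int(rng.integers(0, 80)),
        }
        meta[f"llp{i}"] = {
            "sample_type": "particle", "particle_class": "large_loose_pellet",
            "delay_days": 0.0, "deployment_id": "D1",
        }
        counts[f"agg{i}"] = {
            "g1": 40 + int(rng.integers(0, 3)),
            "g2": 40 + int(rng.integers(0, 25)),
            "bg": 920 + int(rng.integers(0, 80)),
        }
        meta[f"agg{i}"] = {
            "sample_type": "particle", "particle_class": "aggregate",
            "delay_days": 0.0, "deployment_id": "D1",
        }
    ds = make_dataset(counts, meta=meta, lineages=lineages)
    return ds, annotate_dataset(ds)


def test_genus_spike_recovered_with_direction():
    ds, ann = contrast_dataset(spike=True)
    table = genus_contrast(ds, ann, "large_loose_pellet", "aggregate", alpha=0.001)
    hits = table[table["significant"]]
    assert list(hits["genus"]) == ["Chloropicon"]
    assert hits.iloc[0]["direction"] == "large_loose_pellet>aggregate"


def test_identical_class_compositions_give_no_hits():
    ds, ann = contrast_dataset(spike=False)
    table = genus_contrast(ds, ann, "large_loose_pellet", "aggregate", alpha=0.001)
    assert not table["significant"].any()
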