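"""Degradation analyses: presence/absence richness, loss rates, contrasts.

Particle DNA degrades between trap recovery and isolation, erasing taxa from
the detectable 18S community at taxon-specific rates.  This module follows
that signal: the non-rarefied table is first filtered to ASVs seen at least
``min_total`` times dataset-wide and binarised; per-particle ASV richness is
then tallied by trophic mode, functional group or genus; percent loss is
measured against same-class, same-deployment particles isolated immediately
(delay 0); and genus-level relative reads are contrasted between particle
classes with Welch t-tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .classify import TrophicAnnotation
from .io import ASVDataset

DEFAULT_MIN_TOTAL = 10


def presence_absence(ds: ASVDataset, min_total: int = DEFAULT_MIN_TOTAL) -> pd.DataFrame:
    """Binary table of ASVs detected at least ``min_total`` times dataset-wide.

    Idempotent, and monotone in ``min_total``: raising the threshold never
    adds an ASV back.
    """
    totals = ds.counts.sum(axis=0)
    keep = totals.index[totals >= min_total]
    return (ds.counts[keep] >= 1).astype(np.int8)


def _group_key(ann: TrophicAnnotation, key: str) -> str:
    if key == "trophic_mode":
        return ann.trophic_mode
    if key == "functional_group":
        return ann.functional_group
    if key == "genus":
        return ann.genus
    raise KeyError(f"unknown group key {key!r}; use trophic_mode|functional_group|genus")


def richness_by(
    pa_table: pd.DataFrame,
    ds: ASVDataset,
    annotations: dict[str, TrophicAnnotation],
    group_key: str = "trophic_mode",
    sample_type: str = "particle",
) -> pd.DataFrame:
    """Per-sample ASV richness within each taxon grouping.

    Returns one record per sample x group with columns (sample_id,
    particle_class, delay_days, deployment_id, group, richness).
    """
    meta = ds.sample_meta
    sample_ids = [
        s for s in pa_table.index if meta.loc[s, "sample_type"] == sample_type
    ]
    groups: dict[str, list[str]] = {}
    for asv in pa_table.columns:
        groups.setdefault(_group_key(annotations[asv], group_key), []).append(asv)
    rows = []
    for s in sample_ids:
        present = pa_table.loc[s]
        for group, asvs in sorted(groups.items()):
            rows.append(
                {
                    "sample_id": s,
                    "particle_class": meta.loc[s, "particle_class"],
                    "delay_days": meta.loc[s, "delay_days"],
                    "deployment_id": meta.loc[s, "deployment_id"],
                    "group": group,
                    "richness": int(present[asvs].sum()),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id",
            "particle_class",
            "delay_days",
            "deployment_id",
            "group",
            "richness",
        ],
    )


def percent_loss(
    records: pd.DataFrame, baseline_delay: float = 0.0
) -> pd.DataFrame:
    """Percent richness loss relative to immediately isolated particles.

    For each delayed particle, loss = 100 * (1 - r / mean(r_baseline)) where
    the baseline is the mean richness of delay-``baseline_delay`` particles
    of the same group, particle class and deployment.  Losses are then
    summarised as mean +/- SD per group x delay across particles.  Negative
    loss (richness rising with delay) is allowed.
    """
    records = records.copy()
    base = records[records["delay_days"] == baseline_delay]
    if base.empty:
        raise ValueError(f"no baseline particles at delay {baseline_delay}")
    base_mean = (
        base.groupby(["group", "particle_class", "deployment_id"])["richness"]
        .mean()
        .rename("baseline_mean")
    )
    delayed = records[records["delay_days"] != baseline_delay].join(
        base_mean, on=["group", "particle_class", "deployment_id"], how="inner"
    )
    zero = delayed["baseline_mean"] == 0
    if zero.all() and len(delayed):
        bad = delayed.loc[zero, "group"].unique().tolist()
        raise ZeroDivisionError(f"zero baseline mean richness for group(s): {bad}")
    if zero.any():
        bad = sorted(delayed.loc[zero, "group"].unique())
        warnings.warn(
            f"dropping zero-baseline group/class/deployment cells for: {bad}"
        )
        delayed = delayed[~zero]
    delayed["percent_loss"] = 100.0 * (1.0 - delayed["richness"] / delayed["baseline_mean"])
    summary = (
        delayed.groupby(["group", "delay_days"])["percent_loss"]
        .agg(mean_percent_loss="mean", sd_percent_loss="std", n="size")
        .reset_index()
    )
    summary["sd_percent_loss"] = summary["sd_percent_loss"].fillna(0.0)
    summary = summary.rename(columns={"group": "taxon_group"})
    summary.attrs["per_particle"] = delayed
    return summary


@dataclass
class WelchResult:
    t: float
    df: float
    p: float


def welch_t(a, b) -> WelchResult:
    """Welch's unequal-variance t-test with Satterthwaite df, two-sided.

    Sign convention: t > 0 when mean(a) > mean(b).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    if np.var(a) == 0 and np.var(b) == 0 and np.mean(a) == np.mean(b):
        return WelchResult(t=0.0, df=float(len(a) + len(b) - 2), p=1.0)
    res = sps.ttest_ind(a, b, equal_var=False)
    return WelchResult(t=float(res.statistic), df=float(res.df), p=float(res.pvalue))


@dataclass
class AnovaResult:
    f: float
    df_between: int
    df_within: int
    p: float


def one_way_anova(groups: dict[str, np.ndarray] | list) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA on richness by particle class."""
    if isinstance(groups, dict):
        arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    else:
        arrays = [np.asarray(v, dtype=float) for v in groups]
    if len(arrays) < 2 or any(len(a) < 2 for a in arrays):
        raise ValueError("need >= 2 groups with n >= 2 each")
    if all(np.var(a) == 0 for a in arrays) and len({a.mean() for a in arrays}) == 1:
        n = sum(len(a) for a in arrays)
        return AnovaResult(f=0.0, df_between=len(arrays) - 1, df_within=n - len(arrays), p=1.0)
    f, p = sps.f_oneway(*arrays)
    n = sum(len(a) for a in arrays)
    return AnovaResult(
        f=float(f), df_between=len(arrays) - 1, df_within=n - len(arrays), p=float(p)
    )


def genus_contrast(
    ds: ASVDataset,
    annotations: dict[str, TrophicAnnotation],
    class_a: str,
    class_b: str,
    alpha: float = 0.001,
    min_total: int = DEFAULT_MIN_TOTAL,
) -> pd.DataFrame:
    """Genera whose relative reads differ between two particle classes.

    ASVs (>= ``min_total`` dataset-wide reads) are grouped at the genus
    level; per-sample relative read abundances are compared between the two
    particle classes with Welch t-tests.  Returns all tested genera with a
    ``significant`` flag at ``alpha`` (no multiplicity correction beyond the
    strict default threshold) and the direction of the difference.
    """
    meta = ds.sample_meta
    ids_a = ds.samples_where(sample_type="particle", particle_class=class_a)
    ids_b = ds.samples_where(sample_type="particle", particle_class=class_b)
    if len(ids_a) < 2 or len(ids_b) < 2:
        raise ValueError("need >= 2 particles in each class")
    totals = ds.counts.sum(axis=0)
    keep = totals.index[totals >= min_total]
    rel = ds.counts[keep].div(ds.counts.sum(axis=1), axis=0).fillna(0.0)
    genus_of = pd.Series({a: annotations[a].genus for a in keep})
    by_genus = rel.T.groupby(genus_of).sum().T

    rows = []
    for genus in by_genus.columns:
        if genus == "NA":
            continue
        a = by_genus.loc[ids_a, genus].to_numpy()
        b = by_genus.loc[ids_b, genus].to_numpy()
        if np.var(a) == 0 and np.var(b) == 0:
            if a.mean() == b.mean():
                continue
            # constant but different: infinitely separated in the t sense
            rows.append(
                {
                    "genus": genus,
                    "t": np.inf if a.mean() > b.mean() else -np.inf,
                    "df": float(len(a) + len(b) - 2),
                    "p": 0.0,
                    "direction": f"{class_a}>{class_b}" if a.mean() > b.mean() else f"{class_b}>{class_a}",
                    "significant": True,
                }
            )
            continue
        res = welch_t(a, b)
        rows.append(
            {
                "genus": genus,
                "t": res.t,
                "df": res.df,
                "p": res.p,
                "direction": f"{class_a}>{class_b}" if res.t > 0 else f"{class_b}>{class_a}",
                "significant": bool(res.p < alpha),
            }
        )
    out = pd.DataFrame(
        rows, columns=["genus", "t", "df", "p", "direction", "significant"]
    )
    out.attrs["alpha"] = alpha
    return out
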