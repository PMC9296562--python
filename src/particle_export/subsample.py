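"""Sample-size and sequencing-depth bias simulations (saturation curves).

Sediment traps collect a stochastic handful of particles; how many isolated
particles are enough for presence-based comparisons across sample types?
``particle_saturation`` re-computes a detection metric on random subsets of
the isolated particles at increasing subset sizes; ``read_depth_sensitivity``
does the same over rarefaction depths.  Each replicate of the particle curve
is a single random particle ordering evaluated on its prefixes, so
union-based recovery metrics are monotone non-decreasing within every
replicate (not only in the mean), and the value at n is distributed as a
uniformly drawn size-n subset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import TrophicAnnotation
from .export import MissingSamplesError, detect_export, pool_presence
from .io import ASVDataset
from .stats import RarefactionError, rarefy

METRICS = ("bulk_recovery", "particle_union_fraction", "exported_asv_fraction")


@dataclass
class SaturationCurve:
    metric: str
    seed: int | None
    values: pd.DataFrame  # long: columns (n, rep, value)
    summary: pd.DataFrame = field(init=False)

    def __post_init__(self) -> None:
        g = self.values.groupby("n")["value"]
        self.summary = pd.DataFrame(
            {
                "n": sorted(self.values["n"].unique()),
                "mean": g.mean().to_numpy(),
                "sd": g.std(ddof=0).to_numpy(),
                "q05": g.quantile(0.05).to_numpy(),
                "q50": g.quantile(0.50).to_numpy(),
                "q95": g.quantile(0.95).to_numpy(),
            }
        )

    def to_frame(self) -> pd.DataFrame:
        out = self.summary.copy()
        out.insert(0, "metric", self.metric)
        return out


def _metric_on_particles(
    ds: ASVDataset,
    annotations: dict[str, TrophicAnnotation],
    station: int,
    metric: str,
    particle_ids: list[str],
    reference: set[str],
    min_reads: int,
) -> float:
    pooled = ds.counts.loc[particle_ids].sum(axis=0)
    union = set(pooled.index[pooled >= min_reads])
    if metric in ("bulk_recovery", "particle_union_fraction"):
        if not reference:
            return 0.0
        return len(union & reference) / len(reference)
    if metric == "exported_asv_fraction":
        keep = [
            s
            for s in ds.sample_ids
            if ds.sample_meta.loc[s, "sample_type"] != "particle"
            or s in set(particle_ids)
        ]
        part = detect_export(ds.subset_samples(keep), annotations, station, min_reads)
        return part.overall_exported_asv_fraction
    raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")


def particle_saturation(
    ds: ASVDataset,
    annotations: dict[str, TrophicAnnotation],
    station: int,
    metric: str = "bulk_recovery",
    n_grid: list[int] | None = None,
    reps: int = 200,
    seed: int | None = None,
    min_reads: int = 1,
) -> SaturationCurve:
    """Detection metric versus number of isolated particles drawn.

    Metrics: ``bulk_recovery`` — fraction of the bulk-trap ASV set recovered
    by the union of the drawn particles; ``particle_union_fraction`` — same
    against the full-particle-set union; ``exported_asv_fraction`` — the
    export analysis rerun with only the drawn particles as trap evidence.
    Draws are without replacement; n values beyond the number of available
    particles are skipped with a warning.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    particles = ds.samples_where(sample_type="particle", station=station)
    if not particles:
        raise MissingSamplesError(f"no particle samples at station {station}")
    n_max = len(particles)
    if n_grid is None:
        n_grid = list(range(1, n_max + 1))
    if not n_grid:
        raise ValueError("empty n_grid")
    usable = [n for n in sorted(set(n_grid)) if 1 <= n <= n_max]
    skipped = sorted(set(n_grid) - set(usable))
    if skipped:
        import warnings

        warnings.warn(f"skipping n beyond available particles: {skipped}")
    if not usable:
        raise ValueError("no usable n in n_grid")

    if metric == "bulk_recovery":
        reference = pool_presence(ds, "bulk_trap", station, min_reads)
    elif metric == "particle_union_fraction":
        reference = pool_presence(ds, "particle", station, min_reads)
    else:
        reference = set()

    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(reps):
        order = list(rng.permutation(particles))
        for n in usable:
            value = _metric_on_particles(
                ds, annotations, station, metric, order[:n], reference, min_reads
            )
            rows.append({"n": n, "rep": rep, "value": float(value)})
    values = pd.DataFrame(rows, columns=["n", "rep", "value"])
    return SaturationCurve(metric=metric, seed=seed, values=values)


def read_depth_sensitivity(
    ds: ASVDataset,
    depths: list[int],
    reps: int = 20,
    seed: int | None = None,
    metric: str = "asv_recovery",
) -> SaturationCurve:
    """Detection metric versus rarefaction depth (sequencing-depth control).

    ``asv_recovery``: fraction of the dataset's detected ASVs still detected
    after rarefying every retained sample to the given depth.  Samples whose
    totals fall below a depth are dropped, exactly as in :func:`~particle_export.stats.rarefy`.
    """
    if metric != "asv_recovery":
        raise ValueError("read_depth_sensitivity supports metric='asv_recovery'")
    if not depths:
        raise ValueError("empty depth grid")
    detected_full = set(ds.counts.columns[(ds.counts.sum(axis=0) >= 1)])
    if not detected_full:
        raise ValueError("dataset has no detected ASVs")
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(reps):
        for depth in sorted(depths):
            try:
                res = rarefy(ds, depth=depth, seed=int(rng.integers(2**31 - 1)))
            except RarefactionError:
                continue
            rare_detected = set(
                res.dataset.counts.columns[res.dataset.counts.sum(axis=0) >= 1]
            )
            rows.append(
                {
                    "n": depth,
                    "rep": rep,
                    "value": len(rare_detected & detected_full) / len(detected_full),
                }
            )
    if not rows:
        raise RarefactionError("all samples below every requested depth")
    values = pd.DataFrame(rows, columns=["n", "rep", "value"])
    return SaturationCurve(metric=metric, seed=seed, values=values)
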