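"""Export detection and size-fraction partitioning of trap-collected ASVs.

The central questions: which surface-seawater phytoplankton ASVs are also
detected in sinking material (bulk trap or individually isolated particles),
what fraction of each functional group's surface reads those exported ASVs
carry, and — for stations with both bulk and isolated-particle samples —
whether each trap-detected ASV sank in the large (>300 um, individually
isolated) or small (bulk-only) size fraction.

Samples of the same type are pooled within a station before any presence
call; "detected" means at least ``min_reads_per_asv`` pooled reads.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .classify import PHYTOPLANKTON, TrophicAnnotation
from .io import ASVDataset

TRAP_TYPES = ("bulk_trap", "particle")


class MissingSamplesError(ValueError):
    """A station lacks the sample type an analysis requires."""


@dataclass
class GroupExport:
    """Per-functional-group export summary at one station."""

    functional_group: str
    exported_asvs: set[str]
    surface_only_asvs: set[str]
    surface_read_share: dict[str, float]  # per surface ASV, sums to 1 within group

    @property
    def surface_asvs(self) -> set[str]:
        return self.exported_asvs | self.surface_only_asvs

    @property
    def exported_asv_fraction(self) -> float:
        n = len(self.surface_asvs)
        return len(self.exported_asvs) / n if n else 0.0

    @property
    def exported_read_share(self) -> float:
        return float(sum(self.surface_read_share[a] for a in self.exported_asvs))


@dataclass
class ExportPartition:
    station: int
    groups: dict[str, GroupExport] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name in sorted(self.groups):
            g = self.groups[name]
            for asv in sorted(g.surface_asvs):
                rows.append(
                    {
                        "station": self.station,
                        "group": name,
                        "asv_id": asv,
                        "exported_flag": int(asv in g.exported_asvs),
                        "surface_read_share": g.surface_read_share[asv],
                    }
                )
        return pd.DataFrame(
            rows,
            columns=["station", "group", "asv_id", "exported_flag", "surface_read_share"],
        )

    def summary(self) -> pd.DataFrame:
        rows = [
            {
                "station": self.station,
                "group": name,
                "n_surface_asvs": len(g.surface_asvs),
                "n_exported_asvs": len(g.exported_asvs),
                "exported_asv_fraction": g.exported_asv_fraction,
                "exported_read_share": g.exported_read_share,
            }
            for name, g in sorted(self.groups.items())
        ]
        return pd.DataFrame(rows)

    @property
    def overall_exported_asv_fraction(self) -> float:
        n_surface = sum(len(g.surface_asvs) for g in self.groups.values())
        n_exported = sum(len(g.exported_asvs) for g in self.groups.values())
        return n_exported / n_surface if n_surface else 0.0


@dataclass
class GroupSizeSplit:
    functional_group: str
    trophic_mode: str
    bulk_asvs: set[str]
    large_particle_asvs: set[str]  # subset of bulk_asvs also in >=1 isolated particle
    particle_only_asvs: set[str]  # in isolated particles but absent from bulk

    @property
    def small_only_asvs(self) -> set[str]:
        return self.bulk_asvs - self.large_particle_asvs

    @property
    def large_fraction(self) -> float:
        return len(self.large_particle_asvs) / len(self.bulk_asvs) if self.bulk_asvs else 0.0


@dataclass
class SizePartition:
    station: int
    groups: dict[str, GroupSizeSplit] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name in sorted(self.groups):
            g = self.groups[name]
            for asv in sorted(g.bulk_asvs | g.particle_only_asvs):
                if asv in g.large_particle_asvs:
                    size_class = "large"
                elif asv in g.bulk_asvs:
                    size_class = "small_only"
                else:
                    size_class = "particle_only"
                rows.append(
                    {
                        "station": self.station,
                        "group": name,
                        "trophic_mode": g.trophic_mode,
                        "asv_id": asv,
                        "size_class": size_class,
                    }
                )
        return pd.DataFrame(
            rows, columns=["station", "group", "trophic_mode", "asv_id", "size_class"]
        )

    def overall_large_fraction(self, trophic_mode: str | None = None) -> float:
        """|bulk ASVs also in isolated particles| / |bulk ASVs|, optionally by mode."""
        groups = [
            g
            for g in self.groups.values()
            if trophic_mode is None or g.trophic_mode == trophic_mode
        ]
        n_bulk = sum(len(g.bulk_asvs) for g in groups)
        n_large = sum(len(g.large_particle_asvs) for g in groups)
        return n_large / n_bulk if n_bulk else 0.0


# ---------------------------------------------------------------------


def pool_presence(
    ds: ASVDataset,
    sample_type: str,
    station: int,
    min_reads_per_asv: int = 1,
    deployment_id: str | None = None,
) -> set[str]:
    """ASVs detected in the pooled samples of one type at one station.

    Pools read counts across all matching samples; an ASV is present iff its
    pooled total is at least ``min_reads_per_asv``.
    """
    conditions = {"sample_type": sample_type, "station": station}
    if deployment_id is not None:
        conditions["deployment_id"] = deployment_id
    ids = ds.samples_where(**conditions)
    if not ids:
        raise MissingSamplesError(
            f"no {sample_type!r} samples at station {station}"
            + (f" (deployment {deployment_id!r})" if deployment_id else "")
        )
    pooled = ds.counts.loc[ids].sum(axis=0)
    return set(pooled.index[pooled >= min_reads_per_asv])


def _trap_detected(
    ds: ASVDataset,
    station: int,
    min_reads_per_asv: int,
    deployment_id: str | None = None,
) -> set[str]:
    detected: set[str] = set()
    found_any = False
    for stype in TRAP_TYPES:
        try:
            detected |= pool_presence(
                ds, stype, station, min_reads_per_asv, deployment_id=deployment_id
            )
            found_any = True
        except MissingSamplesError:
            continue
    if not found_any:
        raise MissingSamplesError(
            f"no trap samples (bulk_trap or particle) at station {station}"
        )
    return detected


def detect_export(
    ds: ASVDataset,
    annotations: dict[str, TrophicAnnotation],
    station: int,
    min_reads_per_asv: int = 1,
    deployment_id: str | None = None,
) -> ExportPartition:
    """Exported surface phytoplankton ASVs and their surface read shares.

    An exported taxon is a phytoplankton ASV detected in pooled surface
    seawater that is also detected in any individually isolated particle or
    bulk trap sample.  Within each functional group, each surface ASV's share
    is its pooled surface reads over the group's total pooled surface reads.
    Heterotrophs are excluded: their presence at depth may reflect
    colonization and growth rather than export.

    ``deployment_id``, when given, restricts the *trap* samples to one
    deployment (seawater is always pooled station-wide).
    """
    seawater_ids = ds.samples_where(sample_type="seawater", station=station)
    if not seawater_ids:
        raise MissingSamplesError(f"no seawater samples at station {station}")
    trap = _trap_detected(ds, station, min_reads_per_asv, deployment_id=deployment_id)

    pooled_sw = ds.counts.loc[seawater_ids].sum(axis=0)
    result = ExportPartition(station=station)
    by_group: dict[str, list[str]] = {}
    for asv, reads in pooled_sw.items():
        if reads < min_reads_per_asv:
            continue
        ann = annotations[asv]
        if ann.trophic_mode != PHYTOPLANKTON:
            continue
        by_group.setdefault(ann.functional_group, []).append(asv)

    for group, asvs in by_group.items():
        total = float(pooled_sw[asvs].sum())
        if total <= 0:
            warnings.warn(
                f"group {group!r} has zero surface reads at station {station}; omitted"
            )
            continue
        shares = {a: float(pooled_sw[a]) / total for a in asvs}
        exported = {a for a in asvs if a in trap}
        result.groups[group] = GroupExport(
            functional_group=group,
            exported_asvs=exported,
            surface_only_asvs=set(asvs) - exported,
            surface_read_share=shares,
        )
    return result


def partition_by_size(
    ds: ASVDataset,
    annotations: dict[str, TrophicAnnotation],
    station: int,
    min_reads_per_asv: int = 1,
    deployment_id: str | None = None,
) -> SizePartition:
    """Split bulk-trap ASVs into large-particle vs small-fraction-only sets.

    ASVs detected in bulk trap samples but in no individually isolated
    particle are assumed packaged in material not selected for isolation
    (<300 um particles, swimmers, single cells).  Both trophic modes are
    partitioned.  Stations without bulk samples cannot support this analysis
    (the paper's Station 1 situation) and raise :class:`MissingSamplesError`.
    """
    try:
        bulk = pool_presence(
            ds, "bulk_trap", station, min_reads_per_asv, deployment_id=deployment_id
        )
    except MissingSamplesError as exc:
        raise MissingSamplesError(
            f"size partitioning is undefined at station {station}: no bulk "
            f"sediment trap samples are available ({exc})"
        ) from exc
    particles = pool_presence(
        ds, "particle", station, min_reads_per_asv, deployment_id=deployment_id
    )

    result = SizePartition(station=station)
    keys = {(a.functional_group, a.trophic_mode) for a in annotations.values()}
    for group, mode in sorted(keys):
        members = {
            asv
            for asv, ann in annotations.items()
            if ann.functional_group == group and ann.trophic_mode == mode
        }
        g_bulk = bulk & members
        g_particles = particles & members
        if not g_bulk and not g_particles:
            continue
        result.groups[group] = GroupSizeSplit(
            functional_group=group,
            trophic_mode=mode,
            bulk_asvs=g_bulk,
            large_particle_asvs=g_bulk & g_particles,
            particle_only_asvs=g_particles - g_bulk,
        )
    return result


def deployment_consistency(
    ds: ASVDataset,
    annotations: dict[str, TrophicAnnotation],
    station: int,
    deployment_ids: tuple[str, str] | None = None,
    min_reads_per_asv: int = 1,
) -> pd.DataFrame:
    """Per-group |Delta exported_read_share| between two trap deployments.

    The robustness check behind pooling a station's deployments: if the two
    independently collected trap communities imply similar exported read
    shares, stochastic particle collection did not drive the result.
    Returns a frame with per-group deltas; ``attrs['max_delta']`` holds the
    maximum over groups.
    """
    if deployment_ids is None:
        trap_ids = ds.samples_where(
            sample_type=set(TRAP_TYPES), station=station
        )
        found = sorted(set(ds.sample_meta.loc[trap_ids, "deployment_id"]) - {"NA"})
        if len(found) < 2:
            raise MissingSamplesError(
                f"station {station} has {len(found)} trap deployment(s); need >=2"
            )
        deployment_ids = tuple(found[:2])

    parts = [
        detect_export(
            ds, annotations, station, min_reads_per_asv, deployment_id=dep
        )
        for dep in deployment_ids
    ]
    groups = sorted(set(parts[0].groups) | set(parts[1].groups))
    rows = []
    for group in groups:
        shares = [
            p.groups[group].exported_read_share if group in p.groups else 0.0
            for p in parts
        ]
        rows.append(
            {
                "station": station,
                "group": group,
                "share_deployment_a": shares[0],
                "share_deployment_b": shares[1],
                "abs_delta": abs(shares[0] - shares[1]),
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["deployment_ids"] = deployment_ids
    out.attrs["max_delta"] = float(out["abs_delta"].max()) if len(out) else 0.0
    return out
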