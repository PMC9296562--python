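"""Synthetic ASV datasets with known export, packaging and decay structure.

The generator emulates the statistical structure the analyses assume: a
surface community whose taxa belong to phytoplankton and heterotroph
functional groups; a known subset of taxa exported in sinking material;
size-dependent packaging (small cells preferentially end up in large,
individually isolatable particles, the largest cells sink within the small
bulk-only fraction); swimmer zooplankton contaminating bulk trap samples
only; and taxon-specific decay that thins the detectable community of
particles isolated after a delay.

Mechanics per sample type:

* seawater — taxon proportions drawn per station (Dirichlet within group,
  group weights from the config), per-sample Dirichlet resampling for
  overdispersion, then a multinomial read draw;
* isolated particles — support restricted to exported taxa assigned to the
  large (>300 um) fraction; a delayed particle first drops each taxon
  independently with probability 1 - exp(-lambda_g * delay);
* bulk trap — all exported taxa (both size fractions) mixed with swimmer
  taxa at a configured read fraction.

Every generated dataset carries a :class:`GroundTruth` so recovery can be
checked exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import classify_asv, default_rules
from .io import ASVDataset, METADATA_COLUMNS, normalize_lineage


class InfeasibleConfigError(ValueError):
    pass


@dataclass
class GroupSpec:
    """One functional group of taxa and its mechanistic parameters."""

    name: str
    lineage_template: str  # semicolon lineage with {genus}/{species} placeholders
    genera: tuple[str, ...]
    n_taxa: int = 20
    surface_weight: float = 0.1  # group's share of surface reads
    concentration: float = 3.0  # Dirichlet alpha for within-group taxon props
    cell_size_range: tuple[float, float] = (2.0, 50.0)  # um, log-uniform
    export_prob: float = 0.25
    decay_rate: float = 0.0  # lambda, d^-1
    swimmer: bool = False  # bulk-only contaminant, absent from seawater/particles


@dataclass
class DeploymentSpec:
    deployment_id: str
    n_bulk: int = 0
    # (particle_class, delay_days) -> particle count
    particles: dict[tuple[str, int], int] = field(default_factory=dict)


@dataclass
class StationSpec:
    station: int
    n_seawater: int = 12
    deployments: list[DeploymentSpec] = field(default_factory=list)


@dataclass
class SimConfig:
    seed: int = 0
    groups: list[GroupSpec] = field(default_factory=list)
    stations: list[StationSpec] = field(default_factory=list)
    read_depth: dict[str, int] = field(
        default_factory=lambda: {"seawater": 60_000, "particle": 40_000, "bulk_trap": 60_000}
    )
    swimmer_read_fraction: float = 0.15
    # P(large | exported, size s) = 1 / (1 + (s / midpoint)^steepness)
    packaging_midpoint_um: float = 50.0
    packaging_steepness: float = 2.0
    seawater_overdispersion: float = 500.0  # Dirichlet concentration scale per sample
    particle_overdispersion: float = 50.0


@dataclass
class GroundTruth:
    taxa: pd.DataFrame  # per-taxon truth attributes, indexed by asv_id
    sample_compositions: pd.DataFrame  # intended proportions pre-multinomial

    def exported_asvs(self, trophic_mode: str | None = None) -> set[str]:
        t = self.taxa
        mask = t["exported"]
        if trophic_mode is not None:
            mask = mask & (t["trophic_mode"] == trophic_mode)
        return set(t.index[mask])

    def size_fraction_of(self, asv_id: str) -> str:
        return self.taxa.loc[asv_id, "size_fraction"]


def _p_large(size_um: float, config: SimConfig) -> float:
    return 1.0 / (1.0 + (size_um / config.packaging_midpoint_um) ** config.packaging_steepness)


def _build_taxa(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    rules = default_rules()
    rows = []
    idx = 0
    for g in config.groups:
        lo, hi = g.cell_size_range
        for i in range(g.n_taxa):
            idx += 1
            asv_id = f"asv{idx:04d}"
            genus = g.genera[i % len(g.genera)]
            species = f"{genus}_sp{i + 1}"
            lineage = g.lineage_template.format(genus=genus, species=species)
            ranks = normalize_lineage(lineage)
            ann = classify_asv(asv_id, ranks, rules)
            size = float(math.exp(rng.uniform(math.log(lo), math.log(hi))))
            exported = (not g.swimmer) and bool(rng.random() < g.export_prob)
            if exported:
                fraction = "large" if rng.random() < _p_large(size, config) else "small"
            elif g.swimmer:
                fraction = "small"  # bulk-only by construction
            else:
                fraction = "NA"
            rows.append(
                {
                    "asv_id": asv_id,
                    "group": g.name,
                    "trophic_mode": ann.trophic_mode,
                    "functional_group": ann.functional_group,
                    "genus": genus,
                    "lineage": ";".join(ranks),
                    "cell_size_um": size,
                    "exported": exported,
                    "size_fraction": fraction,
                    "decay_rate": g.decay_rate,
                    "swimmer": g.swimmer,
                }
            )
    taxa = pd.DataFrame(rows).set_index("asv_id")
    return taxa


def _station_base_props(
    config: SimConfig, taxa: pd.DataFrame, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Surface proportions (swimmers zeroed) and swimmer proportions."""
    surface = np.zeros(len(taxa))
    swimmer = np.zeros(len(taxa))
    pos = {a: i for i, a in enumerate(taxa.index)}
    total_weight = sum(g.surface_weight for g in config.groups if not g.swimmer)
    for g in config.groups:
        members = taxa.index[taxa["group"] == g.name]
        within = rng.dirichlet(np.full(len(members), g.concentration))
        for a, w in zip(members, within):
            if g.swimmer:
                swimmer[pos[a]] = w * g.surface_weight
            else:
                surface[pos[a]] = w * g.surface_weight / total_weight
    if swimmer.sum() > 0:
        swimmer = swimmer / swimmer.sum()
    return surface, swimmer


def _draw_counts(
    props: np.ndarray, depth: int, overdisp: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Dirichlet-resample proportions then draw a multinomial; returns (counts, props)."""
    support = props > 0
    if depth <= 0 or not support.any():
        return np.zeros(len(props), dtype=np.int64), props
    alpha = props[support] * overdisp
    noisy = np.zeros_like(props)
    noisy[support] = rng.dirichlet(np.clip(alpha, 1e-6, None))
    counts = np.zeros(len(props), dtype=np.int64)
    counts[support] = rng.multinomial(depth, noisy[support] / noisy[support].sum())
    return counts, noisy


def simulate(config: SimConfig, seed: int | None = None) -> tuple[ASVDataset, GroundTruth]:
    """Generate a dataset and its ground truth from a :class:`SimConfig`.

    Deterministic given (config, seed); ``seed`` overrides ``config.seed``.
    Raises :class:`InfeasibleConfigError` when isolated particles are
    requested at positive read depth but no exported taxon was assigned to
    the large size fraction.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    if not config.groups or not config.stations:
        raise InfeasibleConfigError("config needs at least one group and one station")
    taxa = _build_taxa(config, rng)
    asv_ids = list(taxa.index)

    exported_mask = taxa["exported"].to_numpy()
    large_mask = exported_mask & (taxa["size_fraction"] == "large").to_numpy()
    n_particles_requested = sum(
        sum(d.particles.values()) for st in config.stations for d in st.deployments
    )
    if (
        n_particles_requested > 0
        and config.read_depth.get("particle", 0) > 0
        and not large_mask.any()
    ):
        raise InfeasibleConfigError(
            "particles requested at positive read depth but no exported taxon "
            "is assigned to the large size fraction"
        )

    count_rows: dict[str, np.ndarray] = {}
    meta_rows: list[dict] = []
    comp_rows: dict[str, np.ndarray] = {}
    depths_cycle = (5.0, 30.0, 60.0)
    size_labels = ("0.2-5um", ">5um")

    for st in config.stations:
        surface, swimmer_props = _station_base_props(config, taxa, rng)

        for i in range(st.n_seawater):
            sid = f"s{st.station}_sw{i + 1:02d}"
            counts, props = _draw_counts(
                surface, config.read_depth["seawater"], config.seawater_overdispersion, rng
            )
            count_rows[sid] = counts
            comp_rows[sid] = props
            meta_rows.append(
                {
                    "sample_id": sid,
                    "station": st.station,
                    "sample_type": "seawater",
                    "particle_class": "NA",
                    "delay_days": np.nan,
                    "deployment_id": "NA",
                    "depth_m": depths_cycle[i % 3],
                    "size_fraction_label": size_labels[i % 2],
                    "preservation": "none",
                }
            )

        for dep in st.deployments:
            # isolated particles: exported-large support, delay-thinned
            for (p_class, delay), n in sorted(dep.particles.items()):
                for j in range(n):
                    sid = f"s{st.station}_{dep.deployment_id}_{p_class}_d{delay}_{j + 1:02d}"
                    base = np.where(large_mask, surface, 0.0)
                    if base.sum() > 0:
                        base = base / base.sum()
                    if delay > 0:
                        retain = rng.random(len(base)) < np.exp(
                            -taxa["decay_rate"].to_numpy() * delay
                        )
                        base = np.where(retain, base, 0.0)
                        if base.sum() > 0:
                            base = base / base.sum()
                    counts, props = _draw_counts(
                        base,
                        config.read_depth["particle"],
                        config.particle_overdispersion,
                        rng,
                    )
                    count_rows[sid] = counts
                    comp_rows[sid] = props
                    meta_rows.append(
                        {
                            "sample_id": sid,
                            "station": st.station,
                            "sample_type": "particle",
                            "particle_class": p_class,
                            "delay_days": float(delay),
                            "deployment_id": dep.deployment_id,
                            "depth_m": 150.0,
                            "size_fraction_label": ">300um",
                            "preservation": "none",
                        }
                    )

            # bulk: exported taxa of both fractions + swimmers
            for j in range(dep.n_bulk):
                sid = f"s{st.station}_{dep.deployment_id}_bulk{j + 1}"
                exported_props = np.where(exported_mask, surface, 0.0)
                if exported_props.sum() > 0:
                    exported_props = exported_props / exported_props.sum()
                sf = config.swimmer_read_fraction if swimmer_props.sum() > 0 else 0.0
                mix = (1.0 - sf) * exported_props + sf * swimmer_props
                counts, props = _draw_counts(
                    mix, config.read_depth["bulk_trap"], config.particle_overdispersion, rng
                )
                count_rows[sid] = counts
                comp_rows[sid] = props
                meta_rows.append(
                    {
                        "sample_id": sid,
                        "station": st.station,
                        "sample_type": "bulk_trap",
                        "particle_class": "NA",
                        "delay_days": np.nan,
                        "deployment_id": dep.deployment_id,
                        "depth_m": 150.0,
                        "size_fraction_label": "bulk",
                        "preservation": "brine" if j % 2 == 0 else "RNAlater",
                    }
                )

    counts = pd.DataFrame.from_dict(count_rows, orient="index", columns=asv_ids)
    counts = counts.astype(np.int64)
    counts.index.name = "sample_id"
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    meta = meta[[c for c in METADATA_COLUMNS if c != "sample_id"]]

    tax_records = {}
    for asv in asv_ids:
        ranks = normalize_lineage(taxa.loc[asv, "lineage"])
        rec = {f"rank{i + 1}": ranks[i] for i in range(8)}
        rec["lineage"] = ";".join(ranks)
        tax_records[asv] = rec
    taxonomy = pd.DataFrame.from_dict(tax_records, orient="index")
    taxonomy.index.name = "asv_id"

    ds = ASVDataset(counts=counts, sample_meta=meta, taxonomy=taxonomy)
    truth = GroundTruth(
        taxa=taxa,
        sample_compositions=pd.DataFrame.from_dict(
            comp_rows, orient="index", columns=asv_ids
        ),
    )
    return ds, truth


# ---------------------------------------------------------------------
# canonical group palette (one group per classification-rule branch)


def default_groups(
    export_prob: float = 0.25,
    decay: dict[str, float] | None = None,
    n_taxa: int = 20,
) -> list[GroupSpec]:
    """Paper-structured functional groups covering every lineage-rule branch.

    Surface weights put ~80% of reads in heterotrophs; decay defaults give
    dinoflagellates the fastest loss, diatoms intermediate, chlorophytes
    none.
    """
    decay = decay or {
        "Dinoflagellata": 0.9,
        "Bacillariophyta": 0.4,
        "Other_Ochrophyta": 0.3,
        "Chlorophyta": 0.0,
        "Hacrobia": 0.3,
        "Alveolata_other": 0.3,
        "Opisthokonta": 0.3,
        "Rhizaria": 0.3,
        "Other_heterotroph": 0.3,
    }
    E = "Eukaryota"
    specs = [
        GroupSpec(
            "Bacillariophyta",
            f"{E};Stramenopiles;Ochrophyta;Bacillariophyta;Bacillariophyceae;Bacillariophyceae_X;{{genus}};{{species}}",
            genera=("Minidiscus", "Cylindrotheca", "Coscinodiscus", "Rhizosolenia"),
            surface_weight=0.05,
            cell_size_range=(4.0, 1000.0),
            decay_rate=decay["Bacillariophyta"],
        ),
        GroupSpec(
            "Other_Ochrophyta",
            f"{E};Stramenopiles;Ochrophyta;Pelagophyceae;Pelagomonadales;Pelagomonadaceae;{{genus}};{{species}}",
            genera=("Pelagomonas", "Aureococcus"),
            surface_weight=0.04,
            cell_size_range=(1.0, 10.0),
            decay_rate=decay["Other_Ochrophyta"],
        ),
        GroupSpec(
            "Dinoflagellata",
            f"{E};Alveolata;Dinoflagellata;Dinophyceae;Gymnodiniales;Gymnodiniaceae;{{genus}};{{species}}",
            genera=("Gyrodinium", "Gymnodinium", "Prorocentrum", "Tripos"),
            surface_weight=0.05,
            cell_size_range=(10.0, 200.0),
            decay_rate=decay["Dinoflagellata"],
        ),
        GroupSpec(
            "Chlorophyta",
            f"{E};Archaeplastida;Chlorophyta;Chloropicophyceae;Chloropicales;Chloropicaceae;{{genus}};{{species}}",
            genera=("Chloropicon", "Prasinoderma", "Ostreococcus"),
            surface_weight=0.04,
            cell_size_range=(1.0, 5.0),
            decay_rate=decay["Chlorophyta"],
        ),
        GroupSpec(
            "Hacrobia",
            f"{E};Hacrobia;Haptophyta;Prymnesiophyceae;Isochrysidales;Noelaerhabdaceae;{{genus}};{{species}}",
            genera=("Emiliania", "Gephyrocapsa"),
            surface_weight=0.02,
            cell_size_range=(2.0, 20.0),
            decay_rate=decay["Hacrobia"],
        ),
        GroupSpec(
            "Alveolata_other",
            f"{E};Alveolata;Dinoflagellata;Syndiniales;Dino-Group-II;Dino-Group-II-Clade-10-and-11;{{genus}};{{species}}",
            genera=("Dino-Group-II-Clade-10", "Dino-Group-I-Clade-1"),
            surface_weight=0.35,
            cell_size_range=(5.0, 50.0),
            export_prob=0.3,
            decay_rate=decay["Alveolata_other"],
        ),
        GroupSpec(
            "Opisthokonta",
            f"{E};Opisthokonta;Metazoa;Arthropoda;Crustacea;Maxillopoda;{{genus}};{{species}}",
            genera=("Oithona", "Calanus"),
            surface_weight=0.20,
            cell_size_range=(100.0, 2000.0),
            export_prob=0.3,
            decay_rate=decay["Opisthokonta"],
        ),
        GroupSpec(
            "Rhizaria",
            f"{E};Rhizaria;Radiolaria;Polycystinea;Spumellaria;Spumellaria_X;{{genus}};{{species}}",
            genera=("Spongosphaera", "Larcopyle"),
            surface_weight=0.10,
            cell_size_range=(50.0, 500.0),
            export_prob=0.3,
            decay_rate=decay["Rhizaria"],
        ),
        GroupSpec(
            "Other_heterotroph",
            f"{E};Stramenopiles;Opalozoa;MAST-3;MAST-3A;MAST-3A_X;{{genus}};{{species}}",
            genera=("MAST-3A", "MAST-3B"),
            surface_weight=0.15,
            cell_size_range=(2.0, 20.0),
            export_prob=0.3,
            decay_rate=decay["Other_heterotroph"],
        ),
        GroupSpec(
            "Opisthokonta_swimmers",
            f"{E};Opisthokonta;Metazoa;Arthropoda;Crustacea;Maxillopoda;{{genus}};{{species}}",
            genera=("Euphausia", "Pleuromamma"),
            n_taxa=10,
            surface_weight=0.15,  # weight within bulk swimmer pool only
            cell_size_range=(500.0, 5000.0),
            export_prob=0.0,
            decay_rate=0.3,
            swimmer=True,
        ),
    ]
    for s in specs:
        s.n_taxa = n_taxa if not s.swimmer else max(2, n_taxa // 2)
        if s.name in {
            "Bacillariophyta",
            "Other_Ochrophyta",
            "Dinoflagellata",
            "Chlorophyta",
            "Hacrobia",
        }:
            s.export_prob = export_prob
    return specs


def paperlike_layout() -> list[StationSpec]:
    """The study's sampling layout: 3 stations, Station 1 without bulk,
    Station 3 with two deployments and 0/1/2-day isolation delays."""
    return [
        StationSpec(
            station=1,
            n_seawater=13,
            deployments=[
                DeploymentSpec(
                    "S1D1",
                    n_bulk=0,
                    particles={
                        ("aggregate", 0): 3,
                        ("dense_detritus", 0): 7,
                        ("long_pellet", 0): 2,
                    },
                )
            ],
        ),
        StationSpec(
            station=2,
            n_seawater=13,
            deployments=[
                DeploymentSpec(
                    "S2D1",
                    n_bulk=2,
                    particles={
                        ("dense_detritus", 0): 3,
                        ("long_pellet", 0): 2,
                        ("large_loose_pellet", 0): 1,
                    },
                )
            ],
        ),
        StationSpec(
            station=3,
            n_seawater=14,
            deployments=[
                DeploymentSpec(
                    "S3D1",
                    n_bulk=2,
                    particles={
                        ("aggregate", 0): 7,
                        ("dense_detritus", 0): 3,
                        ("long_pellet", 0): 1,
                        ("large_loose_pellet", 0): 4,
                        ("aggregate", 2): 5,
                        ("dense_detritus", 2): 4,
                        ("long_pellet", 2): 2,
                        ("large_loose_pellet", 2): 4,
                    },
                ),
                DeploymentSpec(
                    "S3D2",
                    n_bulk=2,
                    particles={
                        ("aggregate", 0): 5,
                        ("dense_detritus", 0): 5,
                        ("long_pellet", 0): 2,
                        ("large_loose_pellet", 0): 3,
                        ("aggregate", 1): 3,
                        ("dense_detritus", 1): 4,
                        ("large_loose_pellet", 1): 5,
                    },
                ),
            ],
        ),
    ]


def paperlike_config(seed: int = 1702, decay: bool = True) -> SimConfig:
    decay_map = None if decay else {g: 0.0 for g in [
        "Dinoflagellata", "Bacillariophyta", "Other_Ochrophyta", "Chlorophyta",
        "Hacrobia", "Alveolata_other", "Opisthokonta", "Rhizaria", "Other_heterotroph",
    ]}
    return SimConfig(
        seed=seed,
        groups=default_groups(decay=decay_map),
        stations=paperlike_layout(),
    )


FIXTURES = ("paperlike", "null", "tiny")


def fixture(name: str, seed: int | None = None) -> tuple[ASVDataset, GroundTruth]:
    """Deterministic named datasets: ``paperlike``, ``null``, ``tiny``."""
    if name == "paperlike":
        return simulate(paperlike_config(), seed=seed)
    if name == "null":
        groups = default_groups(export_prob=0.0, n_taxa=10)
        for g in groups:
            g.export_prob = 0.0
        config = SimConfig(
            seed=7 if seed is None else seed,
            groups=groups,
            stations=[
                StationSpec(
                    station=1,
                    n_seawater=12,
                    deployments=[DeploymentSpec("D1", n_bulk=2, particles={})],
                )
            ],
            swimmer_read_fraction=1.0,  # bulk is pure swimmers: nothing exported
            read_depth={"seawater": 20_000, "particle": 0, "bulk_trap": 20_000},
        )
        return simulate(config, seed=seed)
    if name == "tiny":
        groups = default_groups(n_taxa=2)
        config = SimConfig(
            seed=11 if seed is None else seed,
            groups=groups,
            stations=[
                StationSpec(
                    station=1,
                    n_seawater=4,
                    deployments=[
                        DeploymentSpec(
                            "D1",
                            n_bulk=1,
                            particles={("aggregate", 0): 2, ("large_loose_pellet", 0): 1},
                        )
                    ],
                )
            ],
            read_depth={"seawater": 3_000, "particle": 2_000, "bulk_trap": 3_000},
        )
        return simulate(config, seed=seed)
    raise KeyError(f"unknown fixture {name!r}; choose from {FIXTURES}")
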