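"""Input/output for ASV feature tables, metadata, taxonomy and carbon tables.

The central container is :class:`ASVDataset`: an integer read-count matrix
(samples x ASVs) joined with per-sample metadata and a PR2-style ranked
lineage for every ASV.  Readers validate on construction and refuse to drop
records silently; writers emit tidy TSV with a deterministic column order so
that every stage output round-trips.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

N_RANKS = 8

SAMPLE_TYPES = frozenset({"seawater", "bulk_trap", "particle"})
PARTICLE_CLASSES = frozenset(
    {"aggregate", "dense_detritus", "long_pellet", "large_loose_pellet", "NA"}
)
PRESERVATIONS = frozenset({"none", "brine", "RNAlater", "NA"})

METADATA_COLUMNS = [
    "sample_id",
    "station",
    "sample_type",
    "particle_class",
    "delay_days",
    "deployment_id",
    "depth_m",
    "size_fraction_label",
    "preservation",
]


class ValidationError(ValueError):
    """Raised when an input table violates an ASVDataset invariant."""


def normalize_lineage(lineage: str) -> list[str]:
    """Split a semicolon-delimited lineage and pad/truncate to 8 ranks.

    Unassigned tail ranks become empty strings; whitespace around tokens is
    trimmed.  PR2 v4 uses exactly eight ranks
    (kingdom..species), so every lineage is normalised to that scheme.
    """
    ranks = [tok.strip() for tok in str(lineage).split(";")]
    ranks = ranks[:N_RANKS]
    ranks += [""] * (N_RANKS - len(ranks))
    return ranks


@dataclass
class ASVDataset:
    """Feature table + sample metadata + taxonomy; single source of truth.

    Attributes
    ----------
    counts : pandas.DataFrame
        Integer reads, samples as rows, ASVs as columns.
    sample_meta : pandas.DataFrame
        One row per sample, indexed by sample_id, columns per
        :data:`METADATA_COLUMNS` (minus sample_id).
    taxonomy : pandas.DataFrame
        Indexed by asv_id with columns ``rank1``..``rank8`` and ``lineage``.
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame
    taxonomy: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ---------------------------------------------------

    def validate(self) -> None:
        counts = self.counts
        if counts.index.has_duplicates:
            dups = counts.index[counts.index.duplicated()].tolist()
            raise ValidationError(f"duplicate sample id(s): {dups}")
        if counts.columns.has_duplicates:
            dups = counts.columns[counts.columns.duplicated()].tolist()
            raise ValidationError(f"duplicate ASV id(s): {dups}")
        arr = counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr), atol=0):
                raise ValidationError("non-integer count in feature table")
            self.counts = counts = counts.astype(np.int64)
            arr = counts.to_numpy()
        if (arr < 0).any():
            bad = counts.columns[(arr < 0).any(axis=0)].tolist()
            raise ValidationError(f"negative count in ASV(s): {bad}")

        missing_meta = set(counts.index) - set(self.sample_meta.index)
        if missing_meta:
            raise ValidationError(
                f"sample(s) in counts missing from metadata: {sorted(missing_meta)}"
            )
        missing_tax = set(counts.columns) - set(self.taxonomy.index)
        if missing_tax:
            raise ValidationError(
                f"ASV(s) in counts missing from taxonomy: {sorted(missing_tax)}"
            )
        bad_types = set(self.sample_meta["sample_type"]) - SAMPLE_TYPES
        if bad_types:
            raise ValidationError(f"unknown sample_type value(s): {sorted(bad_types)}")
        bad_classes = set(self.sample_meta["particle_class"].astype(str)) - PARTICLE_CLASSES
        if bad_classes:
            raise ValidationError(
                f"unknown particle_class value(s): {sorted(bad_classes)}"
            )

    # -- convenience selectors ----------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def asv_ids(self) -> list[str]:
        return list(self.counts.columns)

    def samples_where(self, **conditions) -> list[str]:
        """Sample ids whose metadata matches every keyword condition.

        A condition value may be a scalar or a collection of admissible
        values, e.g. ``samples_where(station=3, sample_type="particle")``.
        """
        mask = pd.Series(True, index=self.sample_meta.index)
        for key, value in conditions.items():
            col = self.sample_meta[key]
            if isinstance(value, (set, frozenset, list, tuple)):
                mask &= col.isin(list(value))
            else:
                mask &= col == value
        ids = [s for s in self.sample_meta.index[mask] if s in self.counts.index]
        return ids

    def subset_samples(self, sample_ids) -> "ASVDataset":
        sample_ids = list(sample_ids)
        return ASVDataset(
            counts=self.counts.loc[sample_ids].copy(),
            sample_meta=self.sample_meta.loc[sample_ids].copy(),
            taxonomy=self.taxonomy.copy(),
        )

    def lineage_ranks(self, asv_id: str) -> list[str]:
        row = self.taxonomy.loc[asv_id]
        return [row[f"rank{i}"] for i in range(1, N_RANKS + 1)]


@dataclass
class BiomassTable:
    """Mixed-layer-integrated functional-group biomass, mmol C m^-2."""

    biomass: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for group, value in self.biomass.items():
            if value < 0:
                raise ValidationError(f"negative biomass for group {group!r}")

    def __getitem__(self, group: str) -> float:
        return self.biomass[group]

    def __contains__(self, group: str) -> bool:
        return group in self.biomass


@dataclass
class FluxTable:
    """POC flux per (particle_class, size_fraction), mmol C m^-2 d^-1."""

    flux: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, value in self.flux.items():
            if value < 0:
                raise ValidationError(f"negative flux for {key}")

    def total(self) -> float:
        return float(sum(self.flux.values()))


# ---------------------------------------------------------------------
# readers


def _read_feature_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=0, dtype={0: str})
    first = df.columns[0]
    df = df.set_index(first)
    if first.strip() == "#OTU ID":
        # QIIME2 exports ASVs as rows; transpose to samples-as-rows.
        df = df.T
    df.index = df.index.astype(str)
    df.index.name = "sample_id"
    df.columns = [str(c) for c in df.columns]
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="raise")
        df[col] = vals
    arr = df.to_numpy()
    if not np.allclose(arr, np.round(arr), atol=0):
        raise ValidationError("non-integer count in feature table")
    if (arr < 0).any():
        raise ValidationError("negative count in feature table")
    return df.astype(np.int64)


def _read_taxonomy(path) -> pd.DataFrame:
    tax = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if not {"asv_id", "lineage"}.issubset(tax.columns):
        raise ValidationError("taxonomy.tsv must have columns (asv_id, lineage)")
    if tax["asv_id"].duplicated().any():
        dups = tax.loc[tax["asv_id"].duplicated(), "asv_id"].tolist()
        raise ValidationError(f"duplicate ASV id(s) in taxonomy: {dups}")
    records = {}
    for _, row in tax.iterrows():
        ranks = normalize_lineage(row["lineage"])
        rec = {f"rank{i + 1}": ranks[i] for i in range(N_RANKS)}
        rec["lineage"] = ";".join(ranks)
        records[row["asv_id"]] = rec
    out = pd.DataFrame.from_dict(records, orient="index")
    out.index.name = "asv_id"
    return out


def _read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype=str).fillna("NA")
    missing = set(METADATA_COLUMNS) - set(meta.columns)
    if missing:
        raise ValidationError(f"metadata.tsv missing column(s): {sorted(missing)}")
    if meta["sample_id"].duplicated().any():
        dups = meta.loc[meta["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValidationError(f"duplicate sample id(s) in metadata: {dups}")
    meta = meta.set_index("sample_id")
    meta["station"] = meta["station"].astype(int)
    meta["delay_days"] = meta["delay_days"].where(meta["delay_days"] != "NA")
    meta["delay_days"] = pd.to_numeric(meta["delay_days"], errors="raise")
    meta["depth_m"] = pd.to_numeric(
        meta["depth_m"].where(meta["depth_m"] != "NA"), errors="raise"
    )
    return meta


def read_dataset(feature_table_path, taxonomy_path, metadata_path) -> ASVDataset:
    """Read and cross-validate the TSV trio into an :class:`ASVDataset`."""
    for p in (feature_table_path, taxonomy_path, metadata_path):
        if not Path(p).exists():
            raise FileNotFoundError(p)
    counts = _read_feature_table(feature_table_path)
    taxonomy = _read_taxonomy(taxonomy_path)
    meta = _read_metadata(metadata_path)
    return ASVDataset(counts=counts, sample_meta=meta, taxonomy=taxonomy)


def read_biomass(path) -> BiomassTable:
    df = pd.read_csv(path)
    if not {"functional_group", "biomass_mmolC_m2"}.issubset(df.columns):
        raise ValidationError(
            "biomass.csv must have columns (functional_group, biomass_mmolC_m2)"
        )
    if df["functional_group"].duplicated().any():
        raise ValidationError("duplicate functional_group in biomass table")
    return BiomassTable(
        dict(zip(df["functional_group"], df["biomass_mmolC_m2"].astype(float)))
    )


def read_flux(path) -> FluxTable:
    df = pd.read_csv(path)
    need = {"particle_class", "size_fraction", "flux_mmolC_m2_d"}
    if not need.issubset(df.columns):
        raise ValidationError(f"flux.csv must have columns {sorted(need)}")
    return FluxTable(
        {
            (row.particle_class, row.size_fraction): float(row.flux_mmolC_m2_d)
            for row in df.itertuples()
        }
    )


def read_biom(path) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Read a BIOM feature table (2.x HDF5 or 1.0 JSON dialect).

    Returns a samples-as-rows count table and, when taxonomy metadata is
    embedded, a taxonomy frame in the same layout the TSV reader produces.
    Only the dense essentials of the format are supported: ids, the sparse
    count matrix, and per-observation ``taxonomy`` metadata.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        import h5py

        with h5py.File(path, "r") as h5:
            obs_ids = [x.decode() for x in h5["observation/ids"][:]]
            samp_ids = [x.decode() for x in h5["sample/ids"][:]]
            data = h5["observation/matrix/data"][:]
            indices = h5["observation/matrix/indices"][:]
            indptr = h5["observation/matrix/indptr"][:]
            from scipy.sparse import csr_matrix

            mat = csr_matrix(
                (data, indices, indptr), shape=(len(obs_ids), len(samp_ids))
            )
            counts = pd.DataFrame(
                mat.toarray().T, index=samp_ids, columns=obs_ids
            )
            tax = None
            if "observation/metadata/taxonomy" in h5:
                lineages = h5["observation/metadata/taxonomy"][:]
                tax = _taxonomy_frame_from_lists(obs_ids, lineages)
    except OSError:
        payload = json.loads(path.read_text())
        obs_ids = [o["id"] for o in payload["rows"]]
        samp_ids = [s["id"] for s in payload["columns"]]
        mat = np.zeros((len(obs_ids), len(samp_ids)))
        if payload.get("matrix_type") == "dense":
            mat = np.asarray(payload["data"], dtype=float)
        else:
            for i, j, v in payload["data"]:
                mat[int(i), int(j)] = v
        counts = pd.DataFrame(mat.T, index=samp_ids, columns=obs_ids)
        tax = None
        lineages = [
            (o.get("metadata") or {}).get("taxonomy") for o in payload["rows"]
        ]
        if any(x is not None for x in lineages):
            tax = _taxonomy_frame_from_lists(obs_ids, lineages)
    counts.index.name = "sample_id"
    return counts.astype(np.int64), tax


def _taxonomy_frame_from_lists(obs_ids, lineages) -> pd.DataFrame:
    records = {}
    for asv, lin in zip(obs_ids, lineages):
        if lin is None:
            lin = []
        if isinstance(lin, (bytes, str)):
            toks = [
                t.decode() if isinstance(t, bytes) else t for t in [lin]
            ]
            ranks = normalize_lineage(toks[0])
        else:
            toks = [t.decode() if isinstance(t, bytes) else str(t) for t in lin]
            ranks = normalize_lineage(";".join(toks))
        rec = {f"rank{i + 1}": ranks[i] for i in range(N_RANKS)}
        rec["lineage"] = ";".join(ranks)
        records[asv] = rec
    out = pd.DataFrame.from_dict(records, orient="index")
    out.index.name = "asv_id"
    return out


# ---------------------------------------------------------------------
# tidy writers / readers for stage outputs


def write_dataset(ds: ASVDataset, out_dir) -> dict[str, Path]:
    """Write the TSV trio (feature_table/taxonomy/metadata) for a dataset."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "feature_table": out_dir / "feature_table.tsv",
        "taxonomy": out_dir / "taxonomy.tsv",
        "metadata": out_dir / "metadata.tsv",
    }
    ds.counts.to_csv(paths["feature_table"], sep="\t", index_label="sample_id")
    tax = pd.DataFrame(
        {"asv_id": ds.taxonomy.index, "lineage": ds.taxonomy["lineage"].to_numpy()}
    )
    tax.to_csv(paths["taxonomy"], sep="\t", index=False)
    meta = ds.sample_meta.copy()
    meta.insert(0, "sample_id", meta.index)
    meta = meta[METADATA_COLUMNS]
    meta.to_csv(paths["metadata"], sep="\t", index=False, na_rep="NA")
    paths = {k: v for k, v in paths.items()}
    return paths


def write_tidy(obj, path) -> Path:
    """Write any stage output in its tidy on-disk form (TSV or JSON).

    Dispatches on the object's ``to_frame``/``to_dict`` protocol: results
    exposing ``to_frame()`` become TSV with a deterministic column order;
    nested summaries (``to_dict()`` only) become JSON.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if hasattr(obj, "to_frame"):
        frame = obj.to_frame()
        frame.to_csv(path, sep="\t", index=False, na_rep="NA")
    elif isinstance(obj, pd.DataFrame):
        obj.to_csv(path, sep="\t", index=False, na_rep="NA")
    elif hasattr(obj, "to_dict"):
        path.write_text(json.dumps(obj.to_dict(), indent=2, sort_keys=True) + "\n")
    else:
        raise TypeError(f"cannot serialise {type(obj).__name__}")
    return path


def read_tidy_frame(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
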