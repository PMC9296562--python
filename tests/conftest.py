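import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from particle_export import ASVDataset, annotate_dataset, fixture

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def make_dataset(counts: dict, meta: dict | None = None, lineages: dict | None = None) -> ASVDataset:
    """Build a small ASVDataset from plain dicts.

    ``counts``: sample_id -> {asv_id: reads}.  Metadata defaults to seawater
    at station 1; ``meta`` overrides per sample (dict of column -> value).
    Lineages default to a diatom lineage.
    """
    count_df = pd.DataFrame.from_dict(counts, orient="index").fillna(0).astype(np.int64)
    count_df.index.name = "sample_id"
    meta = meta or {}
    meta_rows = {}
    for s in count_df.index:
        row = {
            "station": 1,
            "sample_type": "seawater",
            "particle_class": "NA",
            "delay_days": np.nan,
            "deployment_id": "NA",
            "depth_m": 5.0,
            "size_fraction_label": "NA",
            "preservation": "none",
        }
        row.update(meta.get(s, {}))
        meta_rows[s] = row
    meta_df = pd.DataFrame.from_dict(meta_rows, orient="index")
    meta_df.index.name = "sample_id"

    default_lineage = (
        "Eukaryota;Stramenopiles;Ochrophyta;Bacillariophyta;"
        "Bacillariophyceae;Bacillariophyceae_X;Navicula;Navicula_sp"
    )
    lineages = lineages or {}
    tax_rows = {}
    for asv in count_df.columns:
        lin = lineages.get(asv, default_lineage)
        ranks = [t.strip() for t in lin.split(";")]
        ranks = (ranks + [""] * 8)[:8]
        rec = {f"rank{i + 1}": ranks[i] for i in range(8)}
        rec["lineage"] = ";".join(ranks)
        tax_rows[asv] = rec
    tax_df = pd.DataFrame.from_dict(tax_rows, orient="index")
    tax_df.index.name = "asv_id"
    return ASVDataset(counts=count_df, sample_meta=meta_df, taxonomy=tax_df)


PHYTO_LINEAGES = {
    "dino": "Eukaryota;Alveolata;Dinoflagellata;Dinophyceae;Gymnodiniales;Gymnodiniaceae;Gyrodinium;G_sp",
    "synd": "Eukaryota;Alveolata;Dinoflagellata;Syndiniales;Dino-Group-II;Clade-10;DG2;DG2_sp",
    "diatom": "Eukaryota;Stramenopiles;Ochrophyta;Bacillariophyta;Bacillariophyceae;B_X;Minidiscus;M_sp",
    "pelago": "Eukaryota;Stramenopiles;Ochrophyta;Pelagophyceae;Pelagomonadales;P_f;Pelagomonas;P_sp",
    "chloro": "Eukaryota;Archaeplastida;Chlorophyta;Chloropicophyceae;Chloropicales;C_f;Chloropicon;C_sp",
    "hacro": "Eukaryota;Hacrobia;Haptophyta;Prymnesiophyceae;Isochrysidales;N_f;Emiliania;E_sp",
    "opistho": "Eukaryota;Opisthokonta;Metazoa;Arthropoda;Crustacea;Maxillopoda;Calanus;C_sp",
}


@pytest.fixture(scope="session")
def tiny():
    return fixture("tiny")


@pytest.fixture(scope="session")
def paperlike():
    return fixture("paperlike")


@pytest.fixture(scope="session")
def paperlike_annotated(paperlike):
    ds, truth = paperlike
    return ds, truth, annotate_dataset(ds)
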