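"""Community statistics: rarefaction, Bray-Curtis, PERMANOVA, composition.

Rarefaction subsamples each sample's reads to a common depth without
replacement (multivariate hypergeometric draw).  Bray-Curtis dissimilarities
are computed with scipy; PERMANOVA uses the distance-based sum-of-squares
decomposition, so it is exact for arbitrary dissimilarities without
embedding the samples in coordinates.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from .classify import CLASS_RANK, TrophicAnnotation
from .io import ASVDataset

DEFAULT_RAREFACTION_DEPTH = 31_993


class RarefactionError(ValueError):
    pass


@dataclass
class RarefactionResult:
    dataset: ASVDataset
    depth: int
    dropped_samples: list[str]


def rarefy(
    ds: ASVDataset, depth: int = DEFAULT_RAREFACTION_DEPTH, seed: int | None = None
) -> RarefactionResult:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Samples whose total is below ``depth`` are dropped and reported in
    ``dropped_samples`` rather than silently discarded.  A single draw per
    sample with a recorded seed; averaging over draws is available by
    repeating with different seeds.
    """
    if depth < 1:
        raise RarefactionError("rarefaction depth must be >= 1")
    rng = np.random.default_rng(seed)
    totals = ds.counts.sum(axis=1)
    keep = totals[totals >= depth].index.tolist()
    dropped = [s for s in ds.counts.index if s not in set(keep)]
    if not keep:
        raise RarefactionError(f"all samples fall below rarefaction depth {depth}")
    rows = {}
    for sample in keep:
        counts = ds.counts.loc[sample].to_numpy(dtype=np.int64)
        if counts.sum() == depth:
            rows[sample] = counts
        else:
            rows[sample] = rng.multivariate_hypergeometric(counts, depth)
    rare = pd.DataFrame.from_dict(rows, orient="index", dtype=np.int64)
    rare.columns = ds.counts.columns
    rare.index.name = "sample_id"
    out = ASVDataset(
        counts=rare, sample_meta=ds.sample_meta.loc[keep].copy(), taxonomy=ds.taxonomy
    )
    return RarefactionResult(dataset=out, depth=depth, dropped_samples=dropped)


def bray_curtis(ds: ASVDataset) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarities among samples.

    d(i,j) = sum_k |x_ik - x_jk| / sum_k (x_ik + x_jk).  A pair of all-zero
    samples has no defined dissimilarity and raises.
    """
    if len(ds.counts) < 2:
        raise ValueError("need >= 2 samples for a dissimilarity matrix")
    arr = ds.counts.to_numpy(dtype=float)
    if (arr.sum(axis=1) == 0).sum() >= 2:
        raise ValueError("two all-zero samples: Bray-Curtis undefined")
    dm = pdist(arr, metric="braycurtis")
    return DistanceMatrix(squareform(dm), ids=list(ds.counts.index))


@dataclass
class PermanovaResult:
    factor: str
    pseudo_f: float
    p_value: float
    n_permutations: int
    n_samples: int
    n_groups: int
    pairwise: pd.DataFrame | None = None  # columns: group_a, group_b, pseudo_f, p, p_adjusted

    def to_dict(self) -> dict:
        out = {
            "factor": self.factor,
            "pseudo_F": self.pseudo_f,
            "p_value": self.p_value,
            "n_permutations": self.n_permutations,
            "n_samples": self.n_samples,
            "n_groups": self.n_groups,
        }
        if self.pairwise is not None:
            out["pairwise"] = self.pairwise.to_dict(orient="records")
        return out


def _pseudo_f(sq: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    """Distance-based pseudo-F from squared dissimilarities.

    SS_total = sum_{i<j} d_ij^2 / N; SS_within = sum_g (1/n_g) sum_{i<j in g} d_ij^2.
    F = (SS_between / (a-1)) / (SS_within / (N-a)).
    """
    n = len(codes)
    iu = np.triu_indices(n, k=1)
    ss_total = sq[iu].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        if len(idx) > 1:
            sub = sq[np.ix_(idx, idx)]
            ss_within += np.triu(sub, k=1).sum() / len(idx)
    ss_between = ss_total - ss_within
    df_between = n_groups - 1
    df_within = n - n_groups
    if ss_within <= 0:
        return math.inf if ss_between > 0 else 0.0
    return (ss_between / df_between) / (ss_within / df_within)


def permanova(
    dm: DistanceMatrix,
    labels,
    n_perm: int = 999,
    seed: int | None = None,
    exact: bool = False,
    factor: str = "grouping",
) -> PermanovaResult:
    """Permutation MANOVA on a dissimilarity matrix.

    ``labels`` aligns with ``dm.ids`` (a sequence or a mapping id->label).
    p uses the +1 convention: (1 + #{F_perm >= F_obs}) / (1 + n_perm), so it
    never returns 0.  With ``exact=True`` every distinct label permutation
    is enumerated instead (feasible only for small n) and
    p = #{F_perm >= F_obs} / #permutations, counting the identity.
    """
    ids = list(dm.ids)
    if isinstance(labels, dict):
        labels = [labels[i] for i in ids]
    labels = np.asarray(list(labels))
    if len(labels) != len(ids):
        raise ValueError("labels length does not match distance matrix")
    uniq, codes = np.unique(labels, return_inverse=True)
    if len(uniq) < 2:
        raise ValueError("need >= 2 groups for PERMANOVA")
    counts = np.bincount(codes)
    if (counts < 2).any():
        raise ValueError("every group needs >= 2 samples")

    sq = np.asarray(dm.data) ** 2
    f_obs = _pseudo_f(sq, codes, len(uniq))

    if exact:
        n_extreme = 0
        n_total = 0
        for perm in itertools.permutations(codes):
            n_total += 1
            if _pseudo_f(sq, np.asarray(perm), len(uniq)) >= f_obs - 1e-12:
                n_extreme += 1
        p = n_extreme / n_total
        n_perm_used = n_total
    else:
        rng = np.random.default_rng(seed)
        n_extreme = 0
        for _ in range(n_perm):
            perm = rng.permutation(codes)
            if _pseudo_f(sq, perm, len(uniq)) >= f_obs - 1e-12:
                n_extreme += 1
        p = (1 + n_extreme) / (1 + n_perm)
        n_perm_used = n_perm

    return PermanovaResult(
        factor=factor,
        pseudo_f=float(f_obs),
        p_value=float(p),
        n_permutations=n_perm_used,
        n_samples=len(ids),
        n_groups=len(uniq),
    )


def pairwise_permanova(
    dm: DistanceMatrix,
    labels,
    n_perm: int = 999,
    seed: int | None = None,
    factor: str = "grouping",
) -> PermanovaResult:
    """All pairwise PERMANOVAs with Bonferroni adjustment.

    Each pair is tested on its own sub-matrix; adjusted p = min(1, p * C)
    where C is the number of pairs.
    """
    ids = list(dm.ids)
    if isinstance(labels, dict):
        labels = [labels[i] for i in ids]
    labels = np.asarray(list(labels))
    uniq = np.unique(labels)
    if len(uniq) < 3:
        raise ValueError("pairwise testing needs >= 3 groups (use permanova for 2)")
    overall = permanova(dm, labels, n_perm=n_perm, seed=seed, factor=factor)

    pairs = list(itertools.combinations(uniq, 2))
    n_comparisons = len(pairs)
    rng = np.random.default_rng(seed)
    rows = []
    for a, b in pairs:
        mask = np.isin(labels, [a, b])
        sub_ids = [i for i, m in zip(ids, mask) if m]
        sub = dm.filter(sub_ids)
        res = permanova(
            sub,
            labels[mask],
            n_perm=n_perm,
            seed=int(rng.integers(2**31 - 1)),
            factor=factor,
        )
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "pseudo_f": res.pseudo_f,
                "p": res.p_value,
                "p_adjusted": min(1.0, res.p_value * n_comparisons),
            }
        )
    overall.pairwise = pd.DataFrame(rows)
    return overall


def class_composition(
    ds: ASVDataset,
    annotations: dict[str, TrophicAnnotation] | None = None,
    group_cols: tuple[str, ...] = ("sample_type",),
    min_dataset_fraction: float = 0.01,
) -> pd.DataFrame:
    """Mean relative reads per taxonomic Class within sample groups.

    Per-sample relative abundances are averaged within each metadata group
    (default: sample_type; pass e.g. ``("sample_type", "station")`` for the
    per-ecosystem breakdown).  Classes carrying less than
    ``min_dataset_fraction`` of total dataset reads are flagged
    ``excluded_from_plot`` but retained in the table.
    """
    class_of = ds.taxonomy[f"rank{CLASS_RANK}"].replace("", "unassigned")
    rel = ds.counts.div(ds.counts.sum(axis=1), axis=0).fillna(0.0)
    by_class = rel.T.groupby(class_of.loc[rel.columns]).sum().T

    dataset_share = ds.counts.sum(axis=0).groupby(class_of).sum()
    dataset_share = dataset_share / dataset_share.sum()

    meta = ds.sample_meta.loc[by_class.index, list(group_cols)]
    grouped = by_class.join(meta).groupby(list(group_cols)).mean()
    rows = []
    for key, row in grouped.iterrows():
        key = key if isinstance(key, tuple) else (key,)
        for cls, value in row.items():
            rows.append(
                {
                    **dict(zip(group_cols, key)),
                    "taxon_class": cls,
                    "mean_relative_reads": float(value),
                    "dataset_fraction": float(dataset_share.get(cls, 0.0)),
                    "excluded_from_plot": bool(
                        dataset_share.get(cls, 0.0) < min_dataset_fraction
                    ),
                }
            )
    return pd.DataFrame(rows)
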