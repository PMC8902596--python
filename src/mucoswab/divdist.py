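"""Dissimilarities, the measured mucosity factor, alpha diversity, dispersion.

The central quantity is the *mucosity factor*: a swab sample's (squared)
Bray-Curtis dissimilarity to the colon sample collected from the same animal.
Because the colon represents the luminal community while the swab is a
blend of luminal and mucosa-adhered material, this paired distance is a
proxy for how much adhered material the swab picked up.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import mannwhitneyu

from .tablesio import AbundanceTable, PairMap, RelativeAbundanceTable


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric sample x sample dissimilarity matrix."""

    sample_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        n = len(self.sample_ids)
        if v.shape != (n, n):
            raise ValueError("distance matrix shape does not match sample ids")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric within 1e-12")
        if np.any(np.abs(np.diag(v)) > 1e-12):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(v < 0):
            raise ValueError("dissimilarities must be non-negative")

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=list(self.sample_ids), columns=list(self.sample_ids))
        df.index.name = "sample_id"
        return df


def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity 1 - 2*sum(min(x,y)) / (sum(x) + sum(y)).

    Scale-invariant on relative-abundance inputs and bounded in [0, 1];
    0 for identical compositions, 1 for disjoint supports.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be 1-D vectors of equal length")
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("abundances must be non-negative")
    sx, sy = x.sum(), y.sum()
    if sx == 0 or sy == 0:
        raise ValueError("all-zero abundance vector")
    return float(1.0 - 2.0 * np.minimum(x, y).sum() / (sx + sy))


def distance_matrix(table: RelativeAbundanceTable, squared: bool = True) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarities, optionally squared elementwise."""
    d = squareform(pdist(table.values, metric="braycurtis"))
    if squared:
        d = d**2
    return DistanceMatrix(table.sample_ids, d)


def mucosity_measured(
    table: RelativeAbundanceTable, pairs: PairMap, squared: bool = True
) -> pd.Series:
    """Measured mucosity factor per swab: (squared) BC distance to paired colon.

    Returns a float Series indexed by swab sample id; NaN for swabs lacking
    a colon partner. The ``squared`` flag selects squared Bray-Curtis (the
    default) or the plain dissimilarity.
    """
    idx = {s: i for i, s in enumerate(table.sample_ids)}
    out = {}
    for p in pairs:
        if p.swab_id not in idx:
            raise KeyError(f"swab sample {p.swab_id!r} absent from table")
        if p.colon_id is None:
            out[p.swab_id] = np.nan
            continue
        if p.colon_id not in idx:
            raise KeyError(f"paired colon sample {p.colon_id!r} absent from table")
        d = bray_curtis(table.values[idx[p.swab_id]], table.values[idx[p.colon_id]])
        out[p.swab_id] = d**2 if squared else d
    return pd.Series(out, name="mucosity", dtype=float)


def alpha_diversity(table: AbundanceTable) -> pd.DataFrame:
    """Per-sample Shannon index (natural log) and observed-genus richness."""
    rel = table.counts / table.counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(rel > 0, rel * np.log(rel), 0.0)
    shannon = -plogp.sum(axis=1)
    richness = (table.counts > 0).sum(axis=1)
    return pd.DataFrame(
        {"shannon": shannon, "richness": richness},
        index=pd.Index(list(table.sample_ids), name="sample_id"),
    )


def group_dispersion(dist: DistanceMatrix, groups) -> tuple[pd.Series, float]:
    """Within-group dispersion in principal-coordinate space, plus a test.

    Embeds the dissimilarity matrix by classical scaling, keeps the axes with
    positive eigenvalues, and computes each sample's Euclidean distance to its
    group centroid (PERMDISP-style). Exactly two groups are compared by a
    two-sided Mann-Whitney U test on those distances.

    Returns (per-sample dispersion Series, Mann-Whitney p-value).
    """
    from .ordination import pcoa  # local import to avoid a cycle

    groups = pd.Series(list(groups), index=list(dist.sample_ids))
    counts = groups.value_counts()
    if (counts < 2).any():
        small = counts[counts < 2].index.tolist()
        raise ValueError(f"groups with fewer than 2 samples: {small}")
    res = pcoa(dist)
    coords = res.coordinates  # spans the positive-eigenvalue axes only
    disp = np.empty(len(groups))
    for g in counts.index:
        mask = (groups == g).to_numpy()
        centroid = coords[mask].mean(axis=0)
        disp[mask] = np.linalg.norm(coords[mask] - centroid, axis=1)
    series = pd.Series(disp, index=groups.index, name="dispersion")
    levels = counts.index.tolist()
    if len(levels) != 2:
        raise ValueError("dispersion comparison requires exactly two groups")
    a = series[groups == levels[0]]
    b = series[groups == levels[1]]
    if np.allclose(disp, disp[0]):
        p = 1.0
    else:
        p = float(mannwhitneyu(a, b, alternative="two-sided").pvalue)
    return series, p


def write_distance_matrix(dist: DistanceMatrix, path) -> None:
    dist.to_dataframe().to_csv(path, sep="\t", float_format="%.10g")


def write_mucosity(mucosity: pd.Series, path) -> None:
    df = mucosity.rename_axis("sample_id").reset_index()
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.10g")
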