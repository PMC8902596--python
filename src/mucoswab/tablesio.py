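"""Genus abundance tables, sample metadata, and swab-colon pairing.

Conventions used throughout the package:

* samples are rows, taxa (genera) are columns;
* abundance TSVs have a header row, first column ``sample_id``, remaining
  columns genus counts (non-negative integers);
* metadata TSVs have one row per sample with columns ``sample_id``,
  ``animal_id``, ``sample_type`` (``swab``/``colon``), ``treatment``
  (``EF``/``CON``), ``study``, and optional ``eating_score`` and ``litter``;
* files are UTF-8, tab-separated, with ``NA`` for missing values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SAMPLE_TYPES = ("swab", "colon")
TREATMENTS = ("EF", "CON")

METADATA_COLUMNS = (
    "sample_id",
    "animal_id",
    "sample_type",
    "treatment",
    "study",
    "eating_score",
    "litter",
)


@dataclass(frozen=True)
class AbundanceTable:
    """Samples x genera matrix of read counts.

    Parameters
    ----------
    sample_ids, taxon_ids : tuple of str
        Unique row and column labels.
    counts : ndarray of shape (n_samples, n_taxa)
        Non-negative integer read counts; every row sum must be positive.
    """

    sample_ids: tuple[str, ...]
    taxon_ids: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValueError("counts must be a 2-D samples x taxa matrix")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(counts == np.floor(counts)):
                raise ValueError("counts must be integers")
            counts = counts.astype(np.int64)
        object.__setattr__(self, "counts", counts)
        n, g = counts.shape
        if len(self.sample_ids) != n or len(self.taxon_ids) != g:
            raise ValueError("label lengths do not match matrix shape")
        if n < 2 or g < 2:
            raise ValueError("need at least 2 samples and 2 taxa")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids")
        if len(set(self.taxon_ids)) != g:
            raise ValueError("duplicate taxon ids")
        neg = np.argwhere(counts < 0)
        if neg.size:
            i, j = neg[0]
            raise ValueError(
                f"negative count for sample {self.sample_ids[i]!r}, "
                f"taxon {self.taxon_ids[j]!r}"
            )
        zero = np.flatnonzero(counts.sum(axis=1) == 0)
        if zero.size:
            raise ValueError(f"sample {self.sample_ids[zero[0]]!r} has zero total count")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, index=list(self.sample_ids), columns=list(self.taxon_ids))
        df.index.name = "sample_id"
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "AbundanceTable":
        return cls(tuple(map(str, df.index)), tuple(map(str, df.columns)), df.to_numpy())

    def select_samples(self, sample_ids) -> "AbundanceTable":
        """Subset (and reorder) samples by id."""
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in idx]
        if missing:
            raise KeyError(f"samples not in table: {missing}")
        rows = [idx[s] for s in sample_ids]
        return AbundanceTable(tuple(sample_ids), self.taxon_ids, self.counts[rows])

    def select_taxa(self, taxon_ids) -> "AbundanceTable":
        idx = {t: j for j, t in enumerate(self.taxon_ids)}
        missing = [t for t in taxon_ids if t not in idx]
        if missing:
            raise KeyError(f"taxa not in table: {missing}")
        cols = [idx[t] for t in taxon_ids]
        return AbundanceTable(self.sample_ids, tuple(taxon_ids), self.counts[:, cols])


@dataclass(frozen=True)
class RelativeAbundanceTable:
    """Samples x genera matrix of proportions; each row sums to 1."""

    sample_ids: tuple[str, ...]
    taxon_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        n, g = values.shape
        if len(self.sample_ids) != n or len(self.taxon_ids) != g:
            raise ValueError("label lengths do not match matrix shape")
        if np.any(values < 0) or np.any(values > 1):
            raise ValueError("proportions must lie in [0, 1]")
        if not np.allclose(values.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("every row must sum to 1 within 1e-9")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=list(self.sample_ids), columns=list(self.taxon_ids))
        df.index.name = "sample_id"
        return df

    def select_samples(self, sample_ids) -> "RelativeAbundanceTable":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [idx[s] for s in sample_ids]
        return RelativeAbundanceTable(tuple(sample_ids), self.taxon_ids, self.values[rows])


@dataclass(frozen=True)
class SampleMetadata:
    """Per-sample design variables with a pairing key (animal id)."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame.copy()
        for col in ("sample_id", "animal_id", "sample_type", "treatment", "study"):
            if col not in df.columns:
                raise ValueError(f"metadata missing required column {col!r}")
            df[col] = df[col].astype(str)
        if "eating_score" not in df.columns:
            df["eating_score"] = np.nan
        df["eating_score"] = pd.to_numeric(df["eating_score"], errors="raise")
        if np.any(df["eating_score"].dropna() < 0):
            raise ValueError("eating_score must be non-negative")
        if "litter" not in df.columns:
            df["litter"] = pd.NA
        if df["sample_id"].duplicated().any():
            dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise ValueError(f"duplicate sample id {dup!r} in metadata")
        bad_type = set(df["sample_type"]) - set(SAMPLE_TYPES)
        if bad_type:
            raise ValueError(f"sample_type must be one of {SAMPLE_TYPES}, got {sorted(bad_type)}")
        bad_trt = set(df["treatment"]) - set(TREATMENTS)
        if bad_trt:
            raise ValueError(f"treatment must be one of {TREATMENTS}, got {sorted(bad_trt)}")
        object.__setattr__(self, "frame", df.reset_index(drop=True))

    def __len__(self) -> int:
        return len(self.frame)

    def subset(self, mask) -> "SampleMetadata":
        return SampleMetadata(self.frame.loc[mask].reset_index(drop=True))

    def for_samples(self, sample_ids) -> "SampleMetadata":
        df = self.frame.set_index("sample_id").loc[list(sample_ids)].reset_index()
        return SampleMetadata(df)

    def require_covers(self, table: AbundanceTable) -> None:
        missing = set(table.sample_ids) - set(self.frame["sample_id"])
        if missing:
            raise ValueError(f"abundance samples missing from metadata: {sorted(missing)[:5]}")


@dataclass(frozen=True)
class Pair:
    animal_id: str
    swab_id: str
    colon_id: str | None  # None marks an unpaired swab


@dataclass(frozen=True)
class PairMap:
    """Swab-colon pairing resolved on (animal_id, study)."""

    pairs: tuple[Pair, ...] = field(default_factory=tuple)

    def __iter__(self):
        return iter(self.pairs)

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def paired(self) -> tuple[Pair, ...]:
        return tuple(p for p in self.pairs if p.colon_id is not None)

    @property
    def unpaired(self) -> tuple[Pair, ...]:
        return tuple(p for p in self.pairs if p.colon_id is None)


def read_abundance(path) -> AbundanceTable:
    """Read a genus count TSV (first column ``sample_id``)."""
    df = pd.read_csv(path, sep="\t", dtype={0: str}, index_col=0)
    if df.index.name != "sample_id":
        raise ValueError(f"first column of {path} must be named 'sample_id', got {df.index.name!r}")
    if df.isna().any().any():
        raise ValueError(f"{path} contains missing or ragged entries")
    for col in df.columns:
        vals = df[col]
        if not np.issubdtype(vals.dtype, np.number):
            raise ValueError(f"non-numeric counts in column {col!r} of {path}")
        frac = vals != np.floor(vals)
        if frac.any():
            row = df.index[frac][0]
            raise ValueError(f"non-integer count for sample {row!r}, taxon {col!r}")
        neg = vals < 0
        if neg.any():
            row = df.index[neg][0]
            raise ValueError(f"negative count for sample {row!r}, taxon {col!r}")
    return AbundanceTable.from_dataframe(df.astype(np.int64))


def write_abundance(table: AbundanceTable, path) -> None:
    table.to_dataframe().to_csv(path, sep="\t")


def read_metadata(path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=["NA"], keep_default_na=False)
    if "eating_score" in df.columns:
        df["eating_score"] = pd.to_numeric(df["eating_score"])
    return SampleMetadata(df)


def write_metadata(meta: SampleMetadata, path) -> None:
    meta.frame.to_csv(path, sep="\t", index=False, na_rep="NA")


def to_relative(table: AbundanceTable) -> RelativeAbundanceTable:
    """Convert counts to per-sample proportions (row-normalise)."""
    totals = table.counts.sum(axis=1)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(f"sample {table.sample_ids[zero[0]]!r} has zero total count")
    values = table.counts / totals[:, None]
    return RelativeAbundanceTable(table.sample_ids, table.taxon_ids, values)


def filter_taxa(
    table: AbundanceTable,
    min_prevalence: float = 0.0,
    min_mean_relative_abundance: float = 0.0,
) -> AbundanceTable:
    """Optional prevalence/abundance filter; the default keeps every taxon."""
    rel = to_relative(table).values
    prevalence = (table.counts > 0).mean(axis=0)
    mean_rel = rel.mean(axis=0)
    keep = (prevalence >= min_prevalence) & (mean_rel >= min_mean_relative_abundance)
    kept = [t for t, k in zip(table.taxon_ids, keep) if k]
    if len(kept) < 2:
        raise ValueError("filter removed all but <2 taxa")
    return table.select_taxa(kept)


def pair_samples(meta: SampleMetadata) -> PairMap:
    """Resolve swab-colon pairs on (animal_id, study).

    Swabs without a colon partner are returned with ``colon_id=None``;
    animals with a colon sample but no swab are excluded (and logged).
    Two swabs (or two colons) for one animal within one study is an error.
    """
    df = meta.frame
    pairs: list[Pair] = []
    for (animal, _study), grp in df.groupby(["animal_id", "study"], sort=True):
        swabs = grp.loc[grp["sample_type"] == "swab", "sample_id"].tolist()
        colons = grp.loc[grp["sample_type"] == "colon", "sample_id"].tolist()
        if len(swabs) > 1:
            raise ValueError(f"ambiguous pairing: animal {animal!r} has {len(swabs)} swabs")
        if len(colons) > 1:
            raise ValueError(f"ambiguous pairing: animal {animal!r} has {len(colons)} colons")
        if not swabs:
            if colons:
                logger.info("animal %r has a colon sample but no swab; excluded", animal)
            continue
        pairs.append(Pair(str(animal), swabs[0], colons[0] if colons else None))
    return PairMap(tuple(pairs))
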