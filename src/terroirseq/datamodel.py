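"""Shared data model: count tables, sample metadata, distance matrices.

Conventions used throughout the package:

* On disk, count tables are TSV with features as rows and samples as
  columns; the first column holds the feature id and optional
  ``taxonomy`` / ``organism`` annotation columns precede the sample
  columns.
* In memory, statistical routines operate on samples-in-rows arrays;
  :class:`CountTable` stores the on-disk orientation (features x samples)
  and exposes helpers that transpose.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MARKERS = ("16S", "ITS", "mRNA")

#: Organelle lineage prefixes removed before any 16S statistics.  These are
#: plant chloroplast and mitochondrial ribosomal sequences that amplify with
#: bacterial 16S primers in grape must but are not bacteria.
ORGANELLE_LINEAGES = (
    "Bacteria;Cyanobacteria;Cyanobacteriia;Chloroplast",
    "Bacteria;Proteobacteria;Alphaproteobacteria;Rickettsiales;Mitochondria",
)

METADATA_DESIGN_COLUMNS = ("site", "region", "vintage", "tank")
METADATA_NUMERIC_COLUMNS = (
    "timepoint_hours",
    "pH",
    "titratable_acidity",
    "malic_acid",
    "NOPA",
    "NH3",
    "precipitation_mm",
    "gdd",
    "latitude_deg",
    "longitude_deg",
)


class ValidationError(ValueError):
    """Raised when an input table violates the data-model invariants."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    s = pd.Index(ids)
    if s.has_duplicates:
        dupes = s[s.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what}: {dupes[:5]}")


def normalize_lineage(taxonomy: str) -> str:
    """Normalize a lineage string to semicolon-delimited ranks.

    Tolerates comma- vs semicolon-delimited dialects and whitespace around
    delimiters; rank names themselves are left untouched (matching is
    case-sensitive downstream).
    """
    parts = [p.strip() for p in taxonomy.replace(",", ";").split(";")]
    return ";".join(p for p in parts if p)


@dataclass
class CountTable:
    """Feature-by-sample table of non-negative integer counts.

    Parameters
    ----------
    counts
        DataFrame with feature ids as index, sample ids as columns,
        integral non-negative entries.
    marker
        One of ``16S`` (bacterial amplicon), ``ITS`` (fungal amplicon) or
        ``mRNA`` (3' tag counts per gene).
    taxonomy
        Optional per-feature semicolon-delimited rank string (amplicons).
    organism
        Optional per-feature organism label (mRNA tables).
    """

    counts: pd.DataFrame
    marker: str
    taxonomy: pd.Series | None = None
    organism: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.marker not in MARKERS:
            raise ValidationError(
                f"invalid marker {self.marker!r}; expected one of {MARKERS}"
            )
        counts = self.counts
        if not isinstance(counts, pd.DataFrame):
            counts = pd.DataFrame(counts)
        _check_unique(counts.index, "feature ids")
        _check_unique(counts.columns, "sample ids")
        values = counts.to_numpy()
        if values.size:
            if not np.issubdtype(values.dtype, np.number):
                raise ValidationError("counts must be numeric")
            if np.isnan(values.astype(float)).any():
                bad = counts.columns[np.isnan(values.astype(float)).any(axis=0)]
                raise ValidationError(f"missing counts in sample(s) {list(bad[:5])}")
            if (values < 0).any():
                bad = counts.index[(values < 0).any(axis=1)]
                raise ValidationError(
                    f"negative counts for feature(s) {list(bad[:5])}"
                )
            if not np.allclose(values, np.round(values)):
                bad = counts.index[
                    (~np.isclose(values, np.round(values))).any(axis=1)
                ]
                raise ValidationError(
                    f"non-integer counts for feature(s) {list(bad[:5])}"
                )
        self.counts = counts.astype(np.int64)
        for attr in ("taxonomy", "organism"):
            ann = getattr(self, attr)
            if ann is not None:
                ann = pd.Series(ann)
                if not ann.index.equals(self.counts.index):
                    ann = ann.reindex(self.counts.index)
                    if ann.isna().any():
                        raise ValidationError(
                            f"{attr} annotation missing for some features"
                        )
                setattr(self, attr, ann.astype(str))

    # -- convenience accessors -------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_features(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def matrix_samples_by_features(self) -> pd.DataFrame:
        """Counts with samples in rows (statistics orientation)."""
        return self.counts.T

    def select_features(self, keep: Iterable[str]) -> "CountTable":
        keep = list(keep)
        return CountTable(
            counts=self.counts.loc[keep],
            marker=self.marker,
            taxonomy=None if self.taxonomy is None else self.taxonomy.loc[keep],
            organism=None if self.organism is None else self.organism.loc[keep],
        )

    def select_samples(self, keep: Sequence[str]) -> "CountTable":
        return CountTable(
            counts=self.counts.loc[:, list(keep)],
            marker=self.marker,
            taxonomy=self.taxonomy,
            organism=self.organism,
        )

    def equals(self, other: "CountTable") -> bool:
        if self.marker != other.marker or not self.counts.equals(other.counts):
            return False
        for attr in ("taxonomy", "organism"):
            a, b = getattr(self, attr), getattr(other, attr)
            if (a is None) != (b is None):
                return False
            if a is not None and not a.equals(b):
                return False
        return True


@dataclass
class SampleMetadata:
    """Per-sample design labels and covariates.

    The frame is indexed by sample id.  Invariant: each site maps to
    exactly one region, and (site, vintage, tank[, timepoint]) identifies a
    sample uniquely.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        frame = self.frame
        _check_unique(frame.index, "sample ids")
        missing = [c for c in METADATA_DESIGN_COLUMNS if c not in frame.columns]
        if missing:
            raise ValidationError(f"metadata missing required columns: {missing}")
        site_regions = frame.groupby("site")["region"].nunique()
        conflicted = site_regions[site_regions > 1]
        if len(conflicted):
            raise ValidationError(
                f"site(s) mapped to multiple regions: {list(conflicted.index[:5])}"
            )
        key_cols = ["site", "vintage", "tank"]
        if "timepoint_hours" in frame.columns:
            key_cols.append("timepoint_hours")
        if frame.duplicated(subset=key_cols).any():
            dupes = frame[frame.duplicated(subset=key_cols)]
            raise ValidationError(
                "duplicate (site, vintage, tank, timepoint) design keys for "
                f"samples {list(dupes.index[:5])}"
            )
        self.frame = frame

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    def labels(self, column: str) -> pd.Series:
        if column not in self.frame.columns:
            raise ValidationError(f"metadata has no column {column!r}")
        return self.frame[column]

    def select_samples(self, keep: Sequence[str]) -> "SampleMetadata":
        return SampleMetadata(self.frame.loc[list(keep)].copy())

    def site_table(self) -> pd.DataFrame:
        """One row per site, with region and any site-level covariates."""
        cols = [
            c
            for c in ("region", "latitude_deg", "longitude_deg")
            if c in self.frame.columns
        ]
        return self.frame.groupby("site")[cols].first()


@dataclass
class DistanceMatrix:
    """Symmetric pairwise dissimilarities with zero diagonal."""

    ids: list[str]
    values: np.ndarray
    metric_name: str = "unknown"

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if values.shape != (n, n):
            raise ValidationError(
                f"distance matrix shape {values.shape} does not match {n} ids"
            )
        if not np.allclose(values, values.T, atol=1e-12):
            raise ValidationError("distance matrix is not symmetric")
        if np.any(np.diag(values) != 0):
            raise ValidationError("distance matrix diagonal must be exactly 0")
        if values.size and values.min() < -1e-12:
            raise ValidationError("distances must be non-negative")
        self.values = values
        self.ids = list(self.ids)

    @property
    def n(self) -> int:
        return len(self.ids)

    def condensed(self) -> np.ndarray:
        """Strictly-lower-triangle vector in scipy condensed order."""
        iu, ju = np.triu_indices(self.n, k=1)
        return self.values[iu, ju]

    def reorder(self, ids: Sequence[str]) -> "DistanceMatrix":
        pos = {s: i for i, s in enumerate(self.ids)}
        idx = np.array([pos[s] for s in ids])
        return DistanceMatrix(list(ids), self.values[np.ix_(idx, idx)], self.metric_name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


def filter_organelle_asvs(table: CountTable) -> tuple[CountTable, list[str]]:
    """Remove plant chloroplast / mitochondrial ASVs from a 16S table.

    Features whose normalized lineage starts with either organelle lineage
    prefix are dropped.  Returns the filtered table and the removed feature
    ids; the removal count is logged.
    """
    if table.taxonomy is None:
        raise ValidationError("organelle filtering requires taxonomy annotation")
    normalized = table.taxonomy.map(normalize_lineage)
    is_organelle = normalized.map(
        lambda lin: any(lin.startswith(pref) for pref in ORGANELLE_LINEAGES)
    )
    removed = list(table.counts.index[is_organelle])
    kept = list(table.counts.index[~is_organelle])
    logger.info("organelle filter removed %d of %d features", len(removed), table.n_features)
    if not kept:
        logger.warning("organelle filter removed every feature; empty table returned")
    return table.select_features(kept), removed


def align_samples(
    table: CountTable, meta: SampleMetadata
) -> tuple[CountTable, SampleMetadata]:
    """Restrict a table and metadata to their common samples, same order.

    The common order follows the table's column order.  Mismatched ids on
    either side are logged; an empty intersection is an error.
    """
    common = [s for s in table.sample_ids if s in set(meta.sample_ids)]
    if not common:
        raise ValidationError("count table and metadata share no sample ids")
    dropped_t = sorted(set(table.sample_ids) - set(common))
    dropped_m = sorted(set(meta.sample_ids) - set(common))
    if dropped_t:
        logger.info("align_samples: dropping %d table-only samples", len(dropped_t))
    if dropped_m:
        logger.info("align_samples: dropping %d metadata-only samples", len(dropped_m))
    return table.select_samples(common), meta.select_samples(common)
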