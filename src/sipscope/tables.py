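"""Shared containers and naming conventions for SIP count tables.

The central exchange format of the pipeline is the :class:`LibraryTable`:
one sequencing library (one gradient pool, amplified or not) holding
per-feature read counts split by read class (SSU rRNA, LSU rRNA, mRNA,
other non-rRNA), with lineage strings and mean GC content carried per
feature.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import DuplicateRecordError

#: Read classes recognised throughout the pipeline.
READ_CLASSES = ("SSU", "LSU", "mRNA", "other")

#: Taxonomic ranks carried in lineage strings (fixed depth 5).
TAXON_RANKS = ("phylum", "class", "order", "family", "genus")

#: Functional ranks for transcript lineages (KEGG-style rollup).
FUNCTION_RANKS = ("category", "pathway", "gene")

#: The four sequenced pools of a SIP experiment.
POOL_LABELS = ("12C-light", "12C-heavy", "13C-light", "13C-heavy")

LINEAGE_SEP = ";"

#: Required columns of the per-library count data frame.
LIBRARY_COLUMNS = ("feature_id", "feature_kind", "class", "lineage", "gc_percent", "count")

FEATURE_KINDS = ("taxon", "transcript")


def join_lineage(labels) -> str:
    """Join ordered lineage labels into the on-disk string form."""
    return LINEAGE_SEP.join(labels)


def split_lineage(lineage: str) -> tuple[str, ...]:
    """Split a lineage string back into ordered labels ('' -> empty tuple)."""
    if not lineage:
        return ()
    return tuple(lineage.split(LINEAGE_SEP))


@dataclass
class LibraryTable:
    """Read counts of one sequencing library, keyed by (feature_id, class).

    Parameters
    ----------
    library_id:
        Unique identifier of the library.
    pool_label:
        Which of the four SIP pools the library was sequenced from
        (one of :data:`POOL_LABELS`).
    amplified:
        Whether the RNA underwent linear amplification before sequencing.
    data:
        Data frame with columns :data:`LIBRARY_COLUMNS`. Zero-count rows are
        not stored; counts are non-negative integers.
    mass_gain:
        Optional fold-gain in RNA mass recorded for amplified libraries
        (metadata only; mass does not affect counts).
    """

    library_id: str
    pool_label: str
    amplified: bool
    data: pd.DataFrame
    mass_gain: float | None = None

    def __post_init__(self):
        df = self.data.reset_index(drop=True).copy()
        missing = [c for c in LIBRARY_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"library {self.library_id!r} missing columns {missing}")
        df = df.loc[:, list(LIBRARY_COLUMNS)]
        if not np.issubdtype(np.asarray(df["count"]).dtype, np.number):
            raise ValueError("counts must be numeric")
        counts = df["count"].to_numpy()
        if (counts < 0).any():
            raise ValueError(f"library {self.library_id!r} has negative counts")
        if not np.allclose(counts, np.round(counts)):
            raise ValueError("counts must be integers")
        df["count"] = counts.astype(np.int64)
        df = df[df["count"] > 0].reset_index(drop=True)
        if df.empty:
            raise ValueError(f"library {self.library_id!r} has no reads")
        bad_class = set(df["class"]) - set(READ_CLASSES)
        if bad_class:
            raise ValueError(f"unknown read classes {sorted(bad_class)}")
        gc = df["gc_percent"].to_numpy(dtype=float)
        if ((gc <= 0) | (gc >= 100)).any():
            raise ValueError("gc_percent must lie in (0, 100)")
        dup = df.duplicated(subset=["feature_id", "class"])
        if dup.any():
            keys = df.loc[dup, ["feature_id", "class"]].to_records(index=False).tolist()
            raise DuplicateRecordError(
                f"library {self.library_id!r}: duplicate (feature_id, class) keys {keys}"
            )
        self.data = df

    # -- convenience accessors -------------------------------------------------

    @property
    def total_reads(self) -> int:
        return int(self.data["count"].sum())

    def class_counts(self) -> pd.Series:
        """Total reads per class, including zero entries for absent classes."""
        counts = self.data.groupby("class")["count"].sum()
        return counts.reindex(READ_CLASSES, fill_value=0).astype(np.int64)

    def subset(self, read_class: str) -> pd.DataFrame:
        """Rows of one read class (possibly empty)."""
        return self.data[self.data["class"] == read_class]

    def with_data(self, data: pd.DataFrame, **changes) -> "LibraryTable":
        """Copy of this library with replaced count data (revalidates)."""
        return replace(self, data=data, **changes)
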