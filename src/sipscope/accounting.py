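"""Per-library read-class accounting and amplified-vs-unamplified comparisons.

Covers the bookkeeping side of a total-RNA SIP experiment: read-class
tallies (SSU / LSU / mRNA / other non-rRNA percentages per library),
count-weighted GC summaries per class, the paired two-tailed t-test used to
compare amplified against unamplified libraries, and rare-transcript
frequency counts.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, MissingClassError
from .tables import LibraryTable, READ_CLASSES

__all__ = [
    "ClassTally",
    "class_tallies",
    "mean_gc_by_class",
    "paired_two_tailed_t",
    "rare_feature_frequency",
    "tally_frame",
    "gc_frame",
]


@dataclass(frozen=True)
class ClassTally:
    """Read counts and percentages per class for one library."""

    library_id: str
    total_reads: int
    counts: dict[str, int]
    percentages: dict[str, float]

    @property
    def pct_non_rrna(self) -> float:
        """Percentage of reads that are neither SSU nor LSU rRNA."""
        return self.percentages["mRNA"] + self.percentages["other"]


def class_tallies(table: LibraryTable) -> ClassTally:
    """Sum counts by read class; percentages are 100 x class / total."""
    if table.data.empty:
        raise InsufficientDataError("empty library table")
    counts = table.class_counts()
    total = int(counts.sum())
    pct = 100.0 * counts / total
    return ClassTally(
        library_id=table.library_id,
        total_reads=total,
        counts={c: int(counts[c]) for c in READ_CLASSES},
        percentages={c: float(pct[c]) for c in READ_CLASSES},
    )


def mean_gc_by_class(table: LibraryTable, read_class: str) -> float:
    """Count-weighted mean GC (%) over features of one read class."""
    if read_class not in READ_CLASSES:
        raise ValueError(f"unknown read class {read_class!r}")
    rows = table.subset(read_class)
    if rows.empty:
        raise MissingClassError(
            f"library {table.library_id!r} has no {read_class} reads"
        )
    return float(np.average(rows["gc_percent"], weights=rows["count"]))


def paired_two_tailed_t(differences) -> tuple[float, int, float]:
    """Student's t-test (paired, two-tailed) on a vector of paired differences.

    Returns ``(t, df, p)`` with ``t = mean(d) / (sd(d) / sqrt(n))`` and
    ``df = n - 1``. All-zero differences give ``t = 0, p = 1``; zero
    variance with a nonzero mean is reported as the degenerate edge
    ``p = 0`` with an infinite t statistic.
    """
    d = np.asarray(list(differences), dtype=float)
    n = d.size
    if n < 2:
        raise InsufficientDataError("paired t-test needs at least 2 pairs")
    df = n - 1
    if np.std(d, ddof=1) == 0.0:
        if d.mean() == 0.0:
            return 0.0, df, 1.0
        return float(np.sign(d.mean()) * np.inf), df, 0.0
    res = stats.ttest_1samp(d, popmean=0.0, alternative="two-sided")
    return float(res.statistic), df, float(res.pvalue)


def rare_feature_frequency(table: LibraryTable, max_count: int) -> int:
    """Number of mRNA features whose summed read count is below ``max_count``.

    Zero-count features are not representable in the table schema, so
    ``max_count=1`` always yields 0.
    """
    if max_count < 1:
        raise ValueError("max_count must be >= 1")
    mrna = table.subset("mRNA")
    if mrna.empty:
        return 0
    totals = mrna.groupby("feature_id")["count"].sum()
    return int((totals < max_count).sum())


# --------------------------------------------------------------------------
# table-shaped exports


def tally_frame(tables) -> pd.DataFrame:
    """Library-by-library tally table (read totals and class percentages)."""
    rows = []
    for t in tables:
        tally = class_tallies(t)
        rows.append(
            {
                "library_id": tally.library_id,
                "total_reads": tally.total_reads,
                "pct_SSU": tally.percentages["SSU"],
                "pct_LSU": tally.percentages["LSU"],
                "pct_nonrRNA": tally.pct_non_rrna,
                "n_mRNA": tally.counts["mRNA"],
            }
        )
    return pd.DataFrame(rows)


def gc_frame(tables) -> pd.DataFrame:
    """Mean GC per (library, class) for classes present in each library."""
    rows = []
    for t in tables:
        for cls in READ_CLASSES:
            if not t.subset(cls).empty:
                rows.append(
                    {
                        "library_id": t.library_id,
                        "class": cls,
                        "mean_gc": mean_gc_by_class(t, cls),
                    }
                )
    return pd.DataFrame(rows)
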