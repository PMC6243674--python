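"""Alpha-diversity summaries of SIP libraries.

Shannon entropy (natural log) and bias-corrected Chao1 richness per
library, plus the heavy-minus-light contrasts per isotope: in a SIP
experiment the heavy pool of the labeled gradient holds the subcommunity
that assimilated the substrate, so its diversity is expected to be lower
than that of the corresponding light pool.

Computations are delegated to scikit-bio's alpha-diversity routines.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skbio.diversity import alpha as _alpha

from .errors import IncompleteDesignError, InsufficientDataError
from .tables import LibraryTable, POOL_LABELS

__all__ = ["DiversitySummary", "shannon", "chao1", "heavy_light_diversity"]


def _validated(counts) -> np.ndarray:
    arr = np.asarray(list(counts) if not isinstance(counts, np.ndarray) else counts)
    arr = np.atleast_1d(arr)
    if arr.size == 0 or not (arr > 0).any():
        raise InsufficientDataError("diversity needs at least one positive count")
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    return arr.astype(np.int64)


def shannon(counts) -> float:
    """Shannon diversity H = -sum p_i ln p_i, in nats."""
    return float(_alpha.shannon(_validated(counts), base=math.e))


def chao1(counts) -> float:
    """Bias-corrected Chao1 richness: S_obs + F1(F1-1) / (2(F2+1)).

    F1 and F2 are singleton and doubleton counts; with no singletons the
    estimate equals observed richness, and the bias-corrected form is safe
    when there are no doubletons.
    """
    return float(_alpha.chao1(_validated(counts), bias_corrected=True))


@dataclass(frozen=True)
class DiversitySummary:
    """Alpha diversity of one library's reads of one class."""

    library_id: str
    shannon: float
    observed_richness: int
    chao1: float


def _summary(table: LibraryTable, read_class: str) -> DiversitySummary:
    rows = table.subset(read_class)
    if rows.empty:
        raise InsufficientDataError(
            f"library {table.library_id!r} has no {read_class} reads"
        )
    counts = rows.groupby("feature_id")["count"].sum().to_numpy()
    return DiversitySummary(
        library_id=table.library_id,
        shannon=shannon(counts),
        observed_richness=int((counts > 0).sum()),
        chao1=chao1(counts),
    )


def heavy_light_diversity(
    libraries, read_class: str = "SSU"
) -> tuple[dict[str, DiversitySummary], dict[str, float]]:
    """Per-pool diversity summaries plus heavy-minus-light Shannon differences.

    ``libraries`` must contain the four pool labels. Returns the summaries
    keyed by pool label and the signed Shannon differences
    (heavy - light) per isotope; a negative difference means the heavy
    pool is less diverse, the expected signature of isotopic labeling.
    """
    if isinstance(libraries, dict):
        tabs = dict(libraries)
    else:
        tabs = {t.pool_label: t for t in libraries}
    missing = [lab for lab in POOL_LABELS if lab not in tabs]
    if missing:
        raise IncompleteDesignError(f"missing pools {missing}")
    summaries = {lab: _summary(tabs[lab], read_class) for lab in POOL_LABELS}
    diffs = {
        iso: summaries[f"{iso}-heavy"].shannon - summaries[f"{iso}-light"].shannon
        for iso in ("12C", "13C")
    }
    return summaries, diffs
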