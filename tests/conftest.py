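"""Shared fixtures and test helpers."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from sipscope.tables import LibraryTable, join_lineage

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_library(
    library_id,
    pool_label,
    rows,
    amplified=False,
):
    """Build a LibraryTable from (feature_id, kind, class, lineage, gc, count) tuples."""
    data = pd.DataFrame(
        rows,
        columns=["feature_id", "feature_kind", "class", "lineage", "gc_percent", "count"],
    )
    return LibraryTable(
        library_id=library_id, pool_label=pool_label, amplified=amplified, data=data
    )


def taxon_row(feature_id, count, *, cls="SSU", gc=55.0, lineage=None):
    lineage = lineage or join_lineage(("p1", "c1", "o1", "f1", feature_id))
    return (feature_id, "taxon", cls, lineage, gc, count)


def transcript_row(feature_id, count, *, gc=58.0, lineage=None):
    lineage = lineage or join_lineage(("cat1", "path1", feature_id))
    return (feature_id, "transcript", "mRNA", lineage, gc, count)


@pytest.fixture
def quartet_libraries():
    """Four-pool toy libraries where genus X has abundance quartet
    (0.30, 0.10, 0.12, 0.10) over SSU reads, Y has (0.1, 0.1, 0.1, 0.1)
    and Z fills the remainder of 100 SSU reads per library."""
    counts = {
        "13C-heavy": {"X": 30, "Y": 10, "Z": 60},
        "13C-light": {"X": 10, "Y": 10, "Z": 80},
        "12C-heavy": {"X": 12, "Y": 10, "Z": 78},
        "12C-light": {"X": 10, "Y": 10, "Z": 80},
    }
    libs = {}
    for label, by_feature in counts.items():
        rows = [taxon_row(f, c) for f, c in by_feature.items()]
        libs[label] = make_library(label, label, rows)
    return libs
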