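"""Validated TSV input/output for every pipeline stage.

All tables are tab-separated UTF-8 with a header row and '.' decimals.
Files written by the pipeline start with a comment line recording the
config hash and seed for provenance; readers skip comment lines.
"""
from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, TableFormatError
from .gradients import GradientFraction, GradientProfile, PoolSpec, build_profile
from .tables import LIBRARY_COLUMNS, LibraryTable

__all__ = [
    "write_tsv",
    "read_tsv",
    "write_community_tsv",
    "write_fraction_tsv",
    "read_fraction_profiles",
    "write_masses_tsv",
    "read_masses_tsv",
    "write_pool_tsv",
    "read_pool_tsv",
    "write_library_tsv",
    "read_library_tsv",
]

_LIBRARY_FILE_COLUMNS = ("library_id", "pool_label", "amplified") + LIBRARY_COLUMNS


def write_tsv(df: pd.DataFrame, path, meta: dict | None = None) -> None:
    """Write a data frame as TSV with an optional provenance comment line."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if meta:
            fh.write("# sipscope " + " ".join(f"{k}={v}" for k, v in meta.items()) + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path, required: tuple[str, ...] = ()) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except pd.errors.EmptyDataError:
        raise InsufficientDataError(f"{path} is empty") from None
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path} is missing required columns {missing}")
    return df


# --------------------------------------------------------------------------
# ground truth


def write_community_tsv(community, path, meta=None) -> None:
    """Community ground truth: one row per taxon."""
    from .tables import join_lineage

    rows = [
        {
            "taxon_id": t.taxon_id,
            "lineage": join_lineage(t.lineage),
            "rel_abundance": t.rel_abundance,
            "gc_percent": t.gc_percent,
            "alpha13C": t.alpha13C,
        }
        for t in community.taxa
    ]
    write_tsv(pd.DataFrame(rows), path, meta)


def write_transcript_tsv(community, path, meta=None) -> None:
    """Transcript ground truth: one row per (taxon, transcript)."""
    from .tables import join_lineage

    rows = [
        {
            "taxon_id": t.taxon_id,
            "function_id": tr.function_id,
            "function_lineage": join_lineage(tr.function_lineage),
            "gc_percent": tr.gc_percent,
            "expr_weight": tr.expr_weight,
        }
        for t in community.taxa
        for tr in t.transcripts
    ]
    write_tsv(pd.DataFrame(rows), path, meta)


# --------------------------------------------------------------------------
# gradient fractions


def write_fraction_tsv(profiles, path, truth: dict | None = None, meta=None) -> None:
    """Fraction table for a set of gradient profiles.

    ``truth`` optionally maps gradient_id to a per-fraction true-mass
    Series (ground truth from the simulator); the column is left empty
    otherwise.
    """
    rows = []
    for profile in profiles:
        for f in profile.fractions:
            true_mass = np.nan
            if truth and f.gradient_id in truth:
                true_mass = float(truth[f.gradient_id][f.fraction_index])
            rows.append(
                {
                    "gradient_id": f.gradient_id,
                    "isotope": profile.isotope,
                    "fraction_index": f.fraction_index,
                    "density_g_ml": f.density,
                    "true_mass_ng": true_mass,
                    "measured_copies": f.measured_copies,
                }
            )
    write_tsv(pd.DataFrame(rows), path, meta)


def read_fraction_profiles(path) -> list[GradientProfile]:
    """Read a fraction TSV back into one profile per gradient."""
    df = read_tsv(
        path,
        required=("gradient_id", "isotope", "fraction_index", "density_g_ml", "measured_copies"),
    )
    if df.empty:
        raise InsufficientDataError(f"{path} contains a header but no fractions")
    profiles = []
    for gid, group in df.groupby("gradient_id", sort=True):
        isotopes = group["isotope"].unique()
        if len(isotopes) != 1:
            raise TableFormatError(f"gradient {gid!r} has mixed isotopes {isotopes}")
        fractions = [
            GradientFraction(
                gradient_id=str(gid),
                fraction_index=int(r.fraction_index),
                density=float(r.density_g_ml),
                measured_copies=float(r.measured_copies),
            )
            for r in group.itertuples()
        ]
        profiles.append(build_profile(fractions, str(isotopes[0])))
    return profiles


# --------------------------------------------------------------------------
# per-taxon fraction masses (simulator ground truth, needed to re-sample reads)


def write_masses_tsv(gradients: dict, path, meta=None) -> None:
    rows = []
    for gid, grad in gradients.items():
        stacked = grad.masses.stack()
        for (taxon_id, fraction_index), mass in stacked.items():
            rows.append(
                {
                    "gradient_id": gid,
                    "fraction_index": int(fraction_index),
                    "taxon_id": taxon_id,
                    "mass_ng": float(mass),
                }
            )
    write_tsv(pd.DataFrame(rows), path, meta)


def read_masses_tsv(path) -> dict[str, pd.DataFrame]:
    df = read_tsv(path, required=("gradient_id", "fraction_index", "taxon_id", "mass_ng"))
    out = {}
    for gid, group in df.groupby("gradient_id", sort=True):
        out[str(gid)] = group.pivot(
            index="taxon_id", columns="fraction_index", values="mass_ng"
        )
    return out


# --------------------------------------------------------------------------
# pools


def write_pool_tsv(pools: dict[str, PoolSpec], profiles, path, meta=None) -> None:
    """Pool assignment table: one row per member fraction."""
    density = {}
    mass = {}
    for profile in profiles:
        for f in profile.fractions:
            density[f.key] = f.density
            mass[f.key] = f.mass
    rows = []
    for label, pool in pools.items():
        for gid, idx in pool.member_fractions:
            rows.append(
                {
                    "pool_label": label,
                    "gradient_id": gid,
                    "fraction_index": idx,
                    "density_g_ml": density.get((gid, idx), np.nan),
                    "mass": mass.get((gid, idx), np.nan),
                }
            )
    write_tsv(pd.DataFrame(rows), path, meta)


def read_pool_tsv(path) -> dict[str, PoolSpec]:
    df = read_tsv(
        path, required=("pool_label", "gradient_id", "fraction_index", "density_g_ml", "mass")
    )
    pools = {}
    for label, group in df.groupby("pool_label", sort=True):
        members = tuple(
            (str(r.gradient_id), int(r.fraction_index)) for r in group.itertuples()
        )
        dens = group["density_g_ml"].astype(float)
        pools[str(label)] = PoolSpec(
            pool_label=str(label),
            density_window=(float(dens.min()), float(dens.max())),
            member_fractions=members,
            pooled_mass=float(group["mass"].sum()),
        )
    return pools


# --------------------------------------------------------------------------
# libraries


def write_library_tsv(tables, path, meta=None) -> None:
    """Concatenate library tables into one TSV (schema: library columns
    prefixed by library_id, pool_label, amplified)."""
    frames = []
    for t in tables:
        df = t.data.copy()
        df.insert(0, "amplified", t.amplified)
        df.insert(0, "pool_label", t.pool_label)
        df.insert(0, "library_id", t.library_id)
        frames.append(df)
    write_tsv(pd.concat(frames, ignore_index=True), path, meta)


def read_library_tsv(path) -> list[LibraryTable]:
    """Read and validate a library TSV into typed tables.

    Malformed rows are reported with their file line numbers (counting the
    header and any leading comment lines).
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        text = fh.read()
    n_comments = 0
    for line in text.splitlines():
        if line.startswith("#"):
            n_comments += 1
        else:
            break
    try:
        df = pd.read_csv(_io.StringIO(text), sep="\t", comment="#")
    except pd.errors.EmptyDataError:
        raise InsufficientDataError(f"{path} is empty") from None
    missing = [c for c in _LIBRARY_FILE_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path} is missing required columns {missing}")
    if df.empty:
        raise InsufficientDataError(f"{path} contains a header but no count rows")
    counts = pd.to_numeric(df["count"], errors="coerce")
    bad = df.index[counts.isna() | (counts < 0)]
    if len(bad):
        lines = [int(i) + n_comments + 2 for i in bad[:5]]  # +2: header + 1-based
        raise TableFormatError(
            f"{path}: invalid (negative or non-numeric) counts at line(s) {lines}"
        )
    tables = []
    for lid, group in df.groupby("library_id", sort=True):
        pool = group["pool_label"].iloc[0]
        amplified = bool(
            group["amplified"].iloc[0] in (True, "True", "true", 1, "1")
        )
        tables.append(
            LibraryTable(
                library_id=str(lid),
                pool_label=str(pool),
                amplified=amplified,
                data=group.loc[:, list(LIBRARY_COLUMNS)].reset_index(drop=True),
            )
        )
    return tables
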