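"""Quantitative density-gradient profiles and sequencing-pool selection.

An isopycnic CsTFA gradient is collected densest-first into numbered
fractions; each fraction has a buoyant density (measured by weighing known
volumes) and an RNA signal (RT-qPCR of bacterial SSU rRNA). From one
unlabeled (12C) and one labeled (13C) profile, four sequencing pools are
selected: 12C-light, 12C-heavy, 13C-light and 13C-heavy. Direct total-RNA
sequencing imposes a minimum RNA mass per pool (~120 ng in the motivating
experiment), so pools are grown greedily from the gradient ends inward —
the "heaviest (or lightest) fractions from which sufficient RNA could be
obtained" rule.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

from .errors import DuplicateRecordError, InsufficientDataError, PoolSelectionError
from .tables import POOL_LABELS

__all__ = [
    "GradientFraction",
    "GradientProfile",
    "PoolSpec",
    "density_from_weighing",
    "build_profile",
    "combine_duplicates",
    "select_pools",
    "DEFAULT_MIN_POOL_MASS_NG",
    "DEFAULT_HEAVY_CUTOFF",
]

#: Minimum RNA mass per pool required for direct sequencing (ng).
DEFAULT_MIN_POOL_MASS_NG = 120.0

#: Density (g/ml) above which a labeled heavy band is expected to sit.
DEFAULT_HEAVY_CUTOFF = 1.815


@dataclass(frozen=True)
class GradientFraction:
    """One collected gradient fraction.

    ``fraction_index`` follows collection order (1 = heaviest); ``density``
    is buoyant density in g/ml; ``measured_copies`` is the qPCR rRNA signal
    (non-negative, arbitrary copy/mass units); ``rna_mass`` optionally holds
    an independently known RNA mass in ng (ground truth in simulations).
    """

    gradient_id: str
    fraction_index: int
    density: float
    measured_copies: float
    rna_mass: float | None = None

    def __post_init__(self):
        if self.density <= 1.0:
            raise ValueError(f"implausible buoyant density {self.density} g/ml")
        if self.measured_copies < 0:
            raise ValueError("measured_copies must be >= 0")
        if self.rna_mass is not None and self.rna_mass < 0:
            raise ValueError("rna_mass must be >= 0")

    @property
    def key(self) -> tuple[str, int]:
        return (self.gradient_id, self.fraction_index)

    @property
    def mass(self) -> float:
        """Mass used for pool selection: the qPCR signal.

        The selection mimics what an experimenter sees at the bench; an
        optional ``rna_mass`` is ground-truth metadata and deliberately not
        used here, so re-running pool selection from a written fraction table
        reproduces pipeline output exactly.
        """
        return self.measured_copies


@dataclass(frozen=True)
class GradientProfile:
    """Density-ordered fractions of one gradient (or pooled duplicates)."""

    gradient_id: str
    isotope: str  # "12C" or "13C"
    fractions: tuple[GradientFraction, ...]

    def __post_init__(self):
        if self.isotope not in ("12C", "13C"):
            raise ValueError(f"isotope must be '12C' or '13C', got {self.isotope!r}")
        if len(self.fractions) < 2:
            raise InsufficientDataError("a gradient profile needs >= 2 fractions")

    @property
    def densities(self) -> list[float]:
        return [f.density for f in self.fractions]


@dataclass(frozen=True)
class PoolSpec:
    """One of the four sequenced pools.

    ``density_window`` is the realized (low, high) density range of member
    fractions; ``member_fractions`` are (gradient_id, fraction_index) keys;
    ``pooled_mass`` is the summed selection mass of the members.
    """

    pool_label: str
    density_window: tuple[float, float]
    member_fractions: tuple[tuple[str, int], ...]
    pooled_mass: float

    def __post_init__(self):
        if self.pool_label not in POOL_LABELS:
            raise ValueError(f"unknown pool label {self.pool_label!r}")
        low, high = self.density_window
        if low > high:
            raise ValueError("density window must satisfy low <= high")

    @property
    def isotope(self) -> str:
        return self.pool_label.split("-")[0]


def density_from_weighing(mass_g: float, volume_ml: float) -> float:
    """Buoyant density (g/ml) from weighing a known fraction volume."""
    if mass_g <= 0 or volume_ml <= 0:
        raise ValueError("mass and volume must both be positive")
    return mass_g / volume_ml


def build_profile(records, isotope: str) -> GradientProfile:
    """Validate and sort gradient fractions into a profile.

    Fractions are sorted by descending density; ties are broken by
    fraction index (lower index = collected earlier = heavier). Duplicate
    (gradient_id, fraction_index) keys raise :class:`DuplicateRecordError`.
    """
    records = list(records)
    if len(records) < 2:
        raise InsufficientDataError("need at least 2 fractions to build a profile")
    seen = set()
    for rec in records:
        if rec.key in seen:
            raise DuplicateRecordError(f"duplicate fraction {rec.key}")
        seen.add(rec.key)
    ordered = sorted(records, key=lambda f: (-f.density, f.fraction_index))
    gids = sorted({r.gradient_id for r in records})
    return GradientProfile("+".join(gids), isotope, tuple(ordered))


def combine_duplicates(profiles) -> tuple[GradientProfile, dict[int, list[tuple[str, int]]]]:
    """Pool duplicate gradients of one isotope by descending-density rank.

    Fractions are matched across gradients by their density rank (for
    gradients fractionated over the same span this equals matching by
    density window). Returns the combined profile, whose fraction indices
    are ranks 1..n, and a map from rank to the source (gradient_id,
    fraction_index) members, used to expand pool membership back to real
    fractions.
    """
    profiles = list(profiles)
    if not profiles:
        raise InsufficientDataError("no profiles to combine")
    isotopes = {p.isotope for p in profiles}
    if len(isotopes) != 1:
        raise ValueError("can only combine duplicate gradients of one isotope")
    n = len(profiles[0].fractions)
    if any(len(p.fractions) != n for p in profiles):
        raise ValueError("duplicate gradients must have equal fraction counts")
    gid = "+".join(sorted({p.gradient_id for p in profiles}))
    combined = []
    member_map: dict[int, list[tuple[str, int]]] = {}
    for rank in range(n):
        members = [p.fractions[rank] for p in profiles]
        density = sum(f.density for f in members) / len(members)
        measured = sum(f.measured_copies for f in members)
        masses = [f.rna_mass for f in members]
        rna_mass = sum(masses) if all(m is not None for m in masses) else None
        combined.append(
            GradientFraction(gid, rank + 1, density, measured, rna_mass)
        )
        member_map[rank + 1] = [f.key for f in members]
    return GradientProfile(gid, profiles[0].isotope, tuple(combined)), member_map


def _grow_pool(fractions, min_mass: float, forbidden: set) -> tuple[list, float] | None:
    """Greedy contiguous growth from the start of ``fractions``.

    Adds fractions in the given order until cumulative selection mass
    reaches ``min_mass``. Returns None if the run hits a forbidden fraction
    or runs out before reaching the threshold.
    """
    run, cum = [], 0.0
    for frac in fractions:
        if frac.key in forbidden:
            return None
        run.append(frac)
        cum += frac.mass
        if cum >= min_mass:
            return run, cum
    return None


def _window(members) -> tuple[float, float]:
    dens = [f.density for f in members]
    return (min(dens), max(dens))


def select_pools(
    profile_12c: GradientProfile,
    profile_13c: GradientProfile,
    min_mass: float = DEFAULT_MIN_POOL_MASS_NG,
    heavy_cutoff: float = DEFAULT_HEAVY_CUTOFF,
    windows: dict[str, tuple[float, float]] | None = None,
) -> dict[str, PoolSpec]:
    """Select the four sequencing pools from a 12C and a 13C profile.

    Heavy pools grow from the densest fraction inward, light pools from the
    lightest, each stopping at the first fraction where cumulative mass
    reaches ``min_mass``. Pools of one isotope never share a fraction: the
    light pool refuses to grow into the already-selected heavy pool and the
    selection fails with :class:`PoolSelectionError` instead. If the
    13C-heavy pool has to extend below ``heavy_cutoff`` (no dense band, as
    in an unlabeled control experiment) a warning is emitted.

    ``windows`` optionally fixes explicit (low, high) density windows per
    pool label, overriding greedy growth for those pools.
    """
    if min_mass <= 0:
        raise ValueError("min_mass must be positive")
    if profile_12c.isotope != "12C" or profile_13c.isotope != "13C":
        raise ValueError("profiles must be passed as (12C, 13C)")
    windows = windows or {}
    profiles = {"12C": profile_12c, "13C": profile_13c}
    pools: dict[str, PoolSpec] = {}
    taken: dict[str, set] = {"12C": set(), "13C": set()}

    # heavy pools first (the scarce, informative end), then light controls
    for label in ("13C-heavy", "12C-heavy", "13C-light", "12C-light"):
        isotope, side = label.split("-")
        profile = profiles[isotope]
        if label in windows:
            low, high = windows[label]
            members = [f for f in profile.fractions if low <= f.density <= high
                       and f.key not in taken[isotope]]
            if not members:
                raise PoolSelectionError(label, f"no free fractions in window ({low}, {high})")
            mass = sum(f.mass for f in members)
            if mass < min_mass:
                raise PoolSelectionError(
                    label, f"window mass {mass:.1f} below minimum {min_mass:.1f}"
                )
        else:
            if side == "heavy":
                order = sorted(profile.fractions, key=lambda f: (-f.density, f.fraction_index))
            else:
                order = sorted(profile.fractions, key=lambda f: (f.density, -f.fraction_index))
            grown = _grow_pool(order, min_mass, taken[isotope])
            if grown is None:
                raise PoolSelectionError(
                    label,
                    f"cannot reach minimum mass {min_mass:.1f} without exhausting "
                    f"the gradient or colliding with the other {isotope} pool",
                )
            members, mass = grown
        if label == "13C-heavy" and min(f.density for f in members) < heavy_cutoff:
            warnings.warn(
                f"13C-heavy pool extends below the heavy cutoff {heavy_cutoff} g/ml "
                "(no dense band with sufficient RNA; pooling the heaviest fractions "
                "with sufficient RNA instead)",
                stacklevel=2,
            )
        taken[isotope].update(f.key for f in members)
        pools[label] = PoolSpec(
            pool_label=label,
            density_window=_window(members),
            member_fractions=tuple(f.key for f in members),
            pooled_mass=mass,
        )
    return pools
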