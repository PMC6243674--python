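"""Synthetic SIP experiments with known ground truth.

The generator emulates the statistical structure of a total-RNA SIP
study of a contaminated-aquifer microcosm: a bacterial community dominated
by a few families, a subset of taxa fully 13C-labeled, isopycnic
separation of labeled vs unlabeled RNA, seven fractions per gradient,
duplicate gradients pooled into four sequenced libraries, a ~35/64/1 %
SSU/LSU/non-rRNA read mix, and an optional GC-lowering linear-amplification
bias on the mRNA portion.

Buoyant density of a species' RNA follows a linear model

    rho = rho0 + delta_max * alpha + gamma * (GC - gc_ref)

where ``alpha`` is the 13C atom fraction and GC is the rRNA GC content in
percent; within a species, molecules band as a Gaussian of width ``sigma``
truncated to the gradient span.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import EmptyPoolError
from .gradients import GradientFraction, GradientProfile, PoolSpec, build_profile
from .tables import (
    FUNCTION_RANKS,
    LIBRARY_COLUMNS,
    LibraryTable,
    READ_CLASSES,
    TAXON_RANKS,
    join_lineage,
)

__all__ = [
    "TranscriptSpec",
    "TaxonSpec",
    "CommunitySpec",
    "DensityModel",
    "SimConfig",
    "SimulatedGradient",
    "DEFAULT_CLASS_MIX",
    "make_community",
    "mean_density",
    "fractionate",
    "simulate_qpcr",
    "sample_reads",
    "apply_amplification_bias",
]

#: Default read-class proportions (SSU, LSU, mRNA, other non-rRNA).
DEFAULT_CLASS_MIX = (0.35, 0.64, 0.009, 0.001)


@dataclass(frozen=True)
class TranscriptSpec:
    """One functional transcript expressed by a host taxon.

    ``expr_weight`` is the transcript's fraction of the host's mRNA; the
    weights of one taxon sum to 1. ``function_lineage`` is a KEGG-style
    (category, pathway, gene) rollup path.
    """

    function_id: str
    function_lineage: tuple[str, str, str]
    gc_percent: float
    expr_weight: float

    def __post_init__(self):
        if len(self.function_lineage) != len(FUNCTION_RANKS):
            raise ValueError("function_lineage must have depth 3 (category, pathway, gene)")
        if not 0 < self.gc_percent < 100:
            raise ValueError("gc_percent must lie in (0, 100)")
        if self.expr_weight <= 0:
            raise ValueError("expr_weight must be positive")


@dataclass(frozen=True)
class TaxonSpec:
    """One community member: lineage, abundance, rRNA GC and labeling state."""

    taxon_id: str
    lineage: tuple[str, str, str, str, str]
    rel_abundance: float
    gc_percent: float
    alpha13C: float
    transcripts: tuple[TranscriptSpec, ...]

    def __post_init__(self):
        if len(self.lineage) != len(TAXON_RANKS):
            raise ValueError("lineage must have fixed depth 5 (phylum..genus)")
        if self.rel_abundance <= 0:
            raise ValueError("rel_abundance must be positive")
        if not 0 < self.gc_percent < 100:
            raise ValueError("gc_percent must lie in (0, 100)")
        if not 0.0 <= self.alpha13C <= 1.0:
            raise ValueError("alpha13C must lie in [0, 1]")
        if self.transcripts:
            total = sum(t.expr_weight for t in self.transcripts)
            if abs(total - 1.0) > 1e-9:
                raise ValueError("transcript expr_weights must sum to 1")


@dataclass(frozen=True)
class CommunitySpec:
    """A simulated community and its read-class mix."""

    taxa: tuple[TaxonSpec, ...]
    class_mix: tuple[float, float, float, float] = DEFAULT_CLASS_MIX

    def __post_init__(self):
        if not self.taxa:
            raise ValueError("community needs at least one taxon")
        total = sum(t.rel_abundance for t in self.taxa)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"taxon rel_abundances must sum to 1, got {total}")
        if abs(sum(self.class_mix) - 1.0) > 1e-9:
            raise ValueError("class_mix must sum to 1")
        if any(m < 0 for m in self.class_mix):
            raise ValueError("class_mix entries must be non-negative")

    @property
    def class_mix_dict(self) -> dict[str, float]:
        return dict(zip(READ_CLASSES, self.class_mix))

    @property
    def labeled_taxa(self) -> tuple[TaxonSpec, ...]:
        return tuple(t for t in self.taxa if t.alpha13C > 0)

    def with_labeled_alpha(self, alpha: float) -> "CommunitySpec":
        """Copy with the atom fraction of currently labeled taxa set to ``alpha``.

        Used to derive the 12C control arm (``alpha=0``) and partial-labeling
        conditions from one ground-truth community.
        """
        if not 0.0 <= alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        taxa = tuple(
            replace(t, alpha13C=alpha) if t.alpha13C > 0 else t for t in self.taxa
        )
        return replace(self, taxa=taxa)

    def unlabeled(self) -> "CommunitySpec":
        return self.with_labeled_alpha(0.0)


@dataclass(frozen=True)
class DensityModel:
    """Linear buoyant-density model for RNA in a CsTFA gradient.

    Defaults are calibrated so that unlabeled RNA at the reference GC bands
    at 1.7785 g/ml and fully labeled RNA at 1.8260 g/ml (the midpoints of
    the 12C-light and 13C-heavy pool windows of the motivating experiment).
    ``gamma`` gives a weak GC dependence; ``sigma`` is the within-species
    band width, chosen so one species spreads over roughly three of seven
    fractions and partially labeled RNA leaves measurable signal on both
    gradient slopes.
    """

    rho0: float = 1.7785  # g/ml, unlabeled reference density
    delta_max: float = 0.0475  # g/ml shift at alpha = 1
    gamma: float = 0.0004  # g/ml per GC percentage point
    gc_ref: float = 55.0  # reference GC, %
    sigma: float = 0.012  # g/ml within-species band s.d.

    def __post_init__(self):
        if self.rho0 <= 0 or self.delta_max <= 0 or self.sigma <= 0:
            raise ValueError("rho0, delta_max and sigma must be positive")


@dataclass(frozen=True)
class SimConfig:
    """Experiment-scale knobs of the simulator.

    ``read_depth`` is reads per library (the motivating study sequenced
    ~30 million; the desk-scale default is much smaller). ``qpcr_cv`` is the
    coefficient of variation of the multiplicative lognormal qPCR noise.
    ``amp_kappa`` is the strength of the GC-lowering amplification bias,
    per GC percentage point. ``total_rna_ng`` is RNA loaded per gradient.
    """

    seed: int = 0
    n_fractions: int = 7
    gradient_span: tuple[float, float] = (1.755, 1.845)
    read_depth: int = 100_000
    qpcr_cv: float = 0.2
    amp_kappa: float = 0.08
    total_rna_ng: float = 1000.0

    def __post_init__(self):
        if self.n_fractions < 2:
            raise ValueError("n_fractions must be >= 2")
        if self.read_depth < 1:
            raise ValueError("read_depth must be >= 1")
        if self.qpcr_cv < 0:
            raise ValueError("qpcr_cv must be >= 0")
        if self.amp_kappa < 0:
            raise ValueError("amp_kappa must be >= 0")
        low, high = self.gradient_span
        if low >= high:
            raise ValueError("gradient_span must satisfy low < high")


@dataclass(frozen=True)
class SimulatedGradient:
    """Ground truth of one fractionated gradient.

    ``edges`` are the fraction boundaries in descending density order
    (edges[0] is the top of fraction 1, the heaviest); ``masses`` is the
    per-taxon x per-fraction RNA mass matrix in ng (rows: taxon_id,
    columns: fraction_index 1..n).
    """

    gradient_id: str
    isotope: str
    edges: tuple[float, ...]
    masses: pd.DataFrame = field(repr=False)

    def fraction_density(self, index: int) -> float:
        """Midpoint density of fraction ``index`` (1 = heaviest)."""
        return 0.5 * (self.edges[index - 1] + self.edges[index])

    def fraction_total_mass(self) -> pd.Series:
        return self.masses.sum(axis=0)


# --------------------------------------------------------------------------
# community construction


def _nested_labels(rng: np.random.Generator, n_taxa: int):
    """Random but consistent 5-rank hierarchy; genus unique per taxon."""
    n_fam = max(1, round(n_taxa / 3))
    n_ord = max(1, round(n_taxa / 5))
    n_cls = max(1, round(n_taxa / 8))
    n_phy = max(1, round(n_taxa / 12))
    fam_of_taxon = rng.integers(n_fam, size=n_taxa)
    ord_of_fam = rng.integers(n_ord, size=n_fam)
    cls_of_ord = rng.integers(n_cls, size=n_ord)
    phy_of_cls = rng.integers(n_phy, size=n_cls)
    lineages = []
    for i in range(n_taxa):
        f = fam_of_taxon[i]
        o = ord_of_fam[f]
        c = cls_of_ord[o]
        p = phy_of_cls[c]
        lineages.append(
            (f"phy{p + 1}", f"cls{c + 1}", f"ord{o + 1}", f"fam{f + 1}", f"g_t{i + 1:03d}")
        )
    return lineages


def make_community(
    n_taxa: int,
    n_labeled: int,
    seed: int,
    *,
    concentration: float = 0.5,
    class_mix: tuple[float, float, float, float] = DEFAULT_CLASS_MIX,
    max_transcripts: int = 4,
) -> CommunitySpec:
    """Draw a ground-truth community with ``n_labeled`` fully labeled taxa.

    Relative abundances come from a symmetric Dirichlet with concentration
    0.5, a heavy-tailed prior that mimics communities dominated by a few
    families. Each taxon carries 1..``max_transcripts`` functional
    transcripts drawn from a shared category/pathway hierarchy, with
    Dirichlet(1) expression weights. Deterministic given ``seed``.
    """
    if n_taxa < 1:
        raise ValueError("n_taxa must be >= 1")
    if not 0 <= n_labeled <= n_taxa:
        raise ValueError(f"need 0 <= n_labeled <= n_taxa, got {n_labeled} > {n_taxa}")
    rng = np.random.default_rng(seed)
    abund = rng.dirichlet(np.full(n_taxa, concentration))
    abund = np.clip(abund, 1e-12, None)
    abund = abund / abund.sum()
    lineages = _nested_labels(rng, n_taxa)
    labeled = set(rng.choice(n_taxa, size=n_labeled, replace=False).tolist())
    gc = np.clip(rng.normal(55.0, 3.0, size=n_taxa), 40.0, 70.0)

    n_cat, n_path = 4, 8
    cat_of_path = rng.integers(n_cat, size=n_path)
    taxa = []
    for i in range(n_taxa):
        tid = f"t{i + 1:03d}"
        k = int(rng.integers(1, max_transcripts + 1))
        weights = rng.dirichlet(np.ones(k))
        transcripts = []
        for j in range(k):
            path = int(rng.integers(n_path))
            fid = f"{tid}_K{j + 1:02d}"
            transcripts.append(
                TranscriptSpec(
                    function_id=fid,
                    function_lineage=(f"cat{cat_of_path[path] + 1}", f"path{path + 1}", fid),
                    gc_percent=float(np.clip(rng.normal(58.0, 5.0), 35.0, 75.0)),
                    expr_weight=float(weights[j]),
                )
            )
        taxa.append(
            TaxonSpec(
                taxon_id=tid,
                lineage=lineages[i],
                rel_abundance=float(abund[i]),
                gc_percent=float(gc[i]),
                alpha13C=1.0 if i in labeled else 0.0,
                transcripts=tuple(transcripts),
            )
        )
    return CommunitySpec(taxa=tuple(taxa), class_mix=class_mix)


# --------------------------------------------------------------------------
# banding and fractionation


def mean_density(gc_percent: float, alpha13C: float, model: DensityModel | None = None) -> float:
    """Mean buoyant density (g/ml) of RNA with given GC and 13C atom fraction."""
    model = model or DensityModel()
    if not 0.0 <= alpha13C <= 1.0:
        raise ValueError("alpha13C must lie in [0, 1]")
    if not 0 < gc_percent < 100:
        raise ValueError("gc_percent must lie in (0, 100)")
    return model.rho0 + model.delta_max * alpha13C + model.gamma * (gc_percent - model.gc_ref)


def fractionate(
    community: CommunitySpec,
    model: DensityModel | None = None,
    cfg: SimConfig | None = None,
    *,
    gradient_id: str = "G1",
    isotope: str | None = None,
) -> SimulatedGradient:
    """Distribute each species' RNA mass over equal-width density fractions.

    Mass in a fraction is the integral of the species' Gaussian band over
    the fraction's density interval, renormalized over the gradient span so
    total mass is conserved (bands are truncated at the span edges).
    Fraction 1 is the heaviest, per densest-first collection. A warning is
    emitted if the span does not cover every band mean +/- 3 sigma.
    """
    model = model or DensityModel()
    cfg = cfg or SimConfig()
    low, high = cfg.gradient_span
    if low >= high:
        raise ValueError("gradient_span must satisfy low < high")
    edges = np.linspace(high, low, cfg.n_fractions + 1)  # descending
    rows = {}
    truncated = []
    for taxon in community.taxa:
        mu = mean_density(taxon.gc_percent, taxon.alpha13C, model)
        if mu - 3 * model.sigma < low or mu + 3 * model.sigma > high:
            truncated.append(taxon.taxon_id)
        cdf = norm.cdf(edges, loc=mu, scale=model.sigma)
        in_fraction = cdf[:-1] - cdf[1:]  # edges descend, so cdf descends
        span_mass = cdf[0] - cdf[-1]
        if span_mass <= 0:
            raise ValueError(f"band of {taxon.taxon_id} has no mass inside the span")
        rows[taxon.taxon_id] = (
            taxon.rel_abundance * cfg.total_rna_ng * in_fraction / span_mass
        )
    if truncated:
        warnings.warn(
            f"{len(truncated)} of {len(community.taxa)} bands extend beyond the "
            f"gradient span ({low}, {high}) at +/-3 sigma and are truncated "
            f"(e.g. {truncated[0]})",
            stacklevel=2,
        )
    masses = pd.DataFrame.from_dict(rows, orient="index", columns=range(1, cfg.n_fractions + 1))
    masses = masses.loc[[t.taxon_id for t in community.taxa]]
    if isotope is None:
        isotope = "13C" if any(t.alpha13C > 0 for t in community.taxa) else "12C"
    return SimulatedGradient(gradient_id, isotope, tuple(edges), masses)


def simulate_qpcr(gradient: SimulatedGradient, cv: float, seed: int) -> GradientProfile:
    """Noisy RT-qPCR readout of the total rRNA signal per fraction.

    Measured = true total mass x multiplicative lognormal noise with the
    requested coefficient of variation (mean multiplier 1); ``cv=0``
    returns the truth. Deterministic given ``seed``.
    """
    if cv < 0:
        raise ValueError("cv must be >= 0")
    truth = gradient.fraction_total_mass().to_numpy(dtype=float)
    if cv == 0:
        mult = np.ones_like(truth)
    else:
        rng = np.random.default_rng(seed)
        s2 = np.log1p(cv**2)
        mult = rng.lognormal(mean=-s2 / 2, sigma=np.sqrt(s2), size=truth.size)
    fractions = [
        GradientFraction(
            gradient_id=gradient.gradient_id,
            fraction_index=i + 1,
            density=gradient.fraction_density(i + 1),
            measured_copies=float(truth[i] * mult[i]),
            rna_mass=None,
        )
        for i in range(truth.size)
    ]
    return build_profile(fractions, gradient.isotope)


# --------------------------------------------------------------------------
# read sampling


def sample_reads(
    pool: PoolSpec,
    gradients: dict[str, SimulatedGradient],
    community: CommunitySpec,
    depth: int,
    seed: int,
) -> LibraryTable:
    """Multinomial read sampling for one sequencing pool.

    Read probability is proportional to (species mass summed over the
    pool's member fractions) x class mix x (for mRNA, the transcript's
    expression weight). Sequencing normalizes input mass, so only the
    composition of the pool matters. Total reads equal ``depth``;
    zero-count rows are dropped.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    mix = community.class_mix_dict
    mass = None
    for gid, idx in pool.member_fractions:
        if gid not in gradients:
            raise KeyError(f"pool references unknown gradient {gid!r}")
        col = gradients[gid].masses[idx]
        mass = col if mass is None else mass.add(col, fill_value=0.0)
    if mass is None or float(mass.sum()) <= 0.0:
        raise EmptyPoolError(f"pool {pool.pool_label} has no RNA mass to sequence")

    feature_rows: list[tuple] = []
    weights: list[float] = []
    for taxon in community.taxa:
        m = float(mass.get(taxon.taxon_id, 0.0))
        lineage = join_lineage(taxon.lineage)
        for cls in ("SSU", "LSU", "other"):
            feature_rows.append((taxon.taxon_id, "taxon", cls, lineage, taxon.gc_percent))
            weights.append(m * mix[cls])
        for tr in taxon.transcripts:
            feature_rows.append(
                (
                    tr.function_id,
                    "transcript",
                    "mRNA",
                    join_lineage(tr.function_lineage),
                    tr.gc_percent,
                )
            )
            weights.append(m * mix["mRNA"] * tr.expr_weight)
    w = np.asarray(weights, dtype=float)
    probs = w / w.sum()
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(depth, probs)
    data = pd.DataFrame(
        feature_rows, columns=["feature_id", "feature_kind", "class", "lineage", "gc_percent"]
    )
    data["count"] = counts
    return LibraryTable(
        library_id=pool.pool_label,
        pool_label=pool.pool_label,
        amplified=False,
        data=data[data["count"] > 0].loc[:, list(LIBRARY_COLUMNS)],
    )


def apply_amplification_bias(
    table: LibraryTable,
    kappa: float,
    seed: int,
    *,
    mass_gain: float = 300.0,
) -> LibraryTable:
    """Resample the mRNA portion of a library under a GC-lowering bias.

    Each mRNA feature gets weight ``w = exp(-kappa * (GC - 50))``; expected
    proportions are re-weighted accordingly and the mRNA read total is
    redrawn multinomially (modelling a stochastic re-prep of the library).
    rRNA classes are untouched — SSU GC was not measurably affected by
    linear amplification in the motivating experiment. ``kappa=0`` returns
    the counts unchanged. The >= ``mass_gain``-fold RNA mass increase of
    linear amplification is recorded as metadata only.
    """
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    data = table.data.copy()
    lib_id = f"{table.library_id}-amp"
    if kappa == 0:
        return table.with_data(data, library_id=lib_id, amplified=True, mass_gain=mass_gain)
    is_mrna = data["class"] == "mRNA"
    mrna = data[is_mrna]
    if mrna.empty:
        return table.with_data(data, library_id=lib_id, amplified=True, mass_gain=mass_gain)
    w = mrna["count"].to_numpy(dtype=float) * np.exp(
        -kappa * (mrna["gc_percent"].to_numpy(dtype=float) - 50.0)
    )
    probs = w / w.sum()
    rng = np.random.default_rng(seed)
    new_counts = rng.multinomial(int(mrna["count"].sum()), probs)
    data.loc[is_mrna, "count"] = new_counts
    data = data[data["count"] > 0]
    return table.with_data(data, library_id=lib_id, amplified=True, mass_gain=mass_gain)
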