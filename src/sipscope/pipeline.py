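"""End-to-end orchestration: simulate -> pool -> tally -> ef -> diversity.

All randomness flows from one root seed through named per-stage
substreams, so any stage can be reproduced independently and two runs
with the same configuration produce byte-identical outputs.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as sio
from .accounting import gc_frame, mean_gc_by_class, paired_two_tailed_t, tally_frame
from .diversity import heavy_light_diversity
from .enrichment import call_labeled, ef_ranking
from .gradients import (
    DEFAULT_HEAVY_CUTOFF,
    DEFAULT_MIN_POOL_MASS_NG,
    PoolSpec,
    combine_duplicates,
    select_pools,
)
from .simulate import (
    CommunitySpec,
    DEFAULT_CLASS_MIX,
    DensityModel,
    SimConfig,
    SimulatedGradient,
    apply_amplification_bias,
    fractionate,
    make_community,
    sample_reads,
    simulate_qpcr,
)
from .tables import POOL_LABELS, LibraryTable

__all__ = ["RunConfig", "SimResult", "substream_seed", "simulate_experiment",
           "analyze_libraries", "run_pipeline", "simulate_and_rank"]

logger = logging.getLogger("sipscope")


def substream_seed(root_seed: int, name: str) -> int:
    """Deterministic per-stage child seed derived from the root seed."""
    key = zlib.crc32(name.encode("utf-8"))
    seq = np.random.SeedSequence(entropy=int(root_seed), spawn_key=(key,))
    return int(seq.generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """Full configuration of one synthetic SIP run.

    Groups the simulator scale (community size, labeling, read depth), the
    density model, the pool-selection constraints and the EF parameters.
    Validated on construction; serialized next to the outputs for
    provenance.
    """

    # experiment design
    n_taxa: int = 20
    n_labeled: int = 5
    alpha13C: float = 1.0
    seed: int = 1
    n_gradients: int = 2  # duplicate gradients per isotope, pooled before sequencing
    # simulator scale
    n_fractions: int = 7
    gradient_span: tuple[float, float] = (1.755, 1.845)
    read_depth: int = 100_000
    qpcr_cv: float = 0.2
    amp_kappa: float = 0.08
    total_rna_ng: float = 1000.0
    class_mix: tuple[float, float, float, float] = DEFAULT_CLASS_MIX
    # density model
    rho0: float = 1.7785
    delta_max: float = 0.0475
    gamma: float = 0.0004
    gc_ref: float = 55.0
    sigma: float = 0.012
    # pool selection
    min_mass: float = DEFAULT_MIN_POOL_MASS_NG
    heavy_cutoff: float = DEFAULT_HEAVY_CUTOFF
    # enrichment parameters
    taxon_level: str = "genus"
    transcript_level: str = "gene"
    min_mean_abundance: float = 0.01
    min_total_reads: int = 20
    pseudo: float | str = "auto"
    ef_call_threshold: float = 1.0
    # output
    out_dir: str | None = None
    log_level: str = "INFO"

    def __post_init__(self):
        if not 0 <= self.n_labeled <= self.n_taxa:
            raise ValueError("need 0 <= n_labeled <= n_taxa")
        if not 0.0 <= self.alpha13C <= 1.0:
            raise ValueError("alpha13C must lie in [0, 1]")
        if self.n_gradients < 1:
            raise ValueError("n_gradients must be >= 1")
        self.gradient_span = tuple(self.gradient_span)  # type: ignore[assignment]
        self.class_mix = tuple(self.class_mix)  # type: ignore[assignment]
        self.density_model()  # validate
        self.sim_config()

    def density_model(self) -> DensityModel:
        return DensityModel(
            rho0=self.rho0, delta_max=self.delta_max, gamma=self.gamma,
            gc_ref=self.gc_ref, sigma=self.sigma,
        )

    def sim_config(self) -> SimConfig:
        return SimConfig(
            seed=self.seed, n_fractions=self.n_fractions,
            gradient_span=self.gradient_span, read_depth=self.read_depth,
            qpcr_cv=self.qpcr_cv, amp_kappa=self.amp_kappa,
            total_rna_ng=self.total_rna_ng,
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["gradient_span"] = list(self.gradient_span)
        d["class_mix"] = list(self.class_mix)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)

    def config_hash(self) -> str:
        payload = {k: v for k, v in self.to_dict().items() if k not in ("out_dir", "log_level")}
        blob = json.dumps(payload, sort_keys=True).encode("utf-8")
        return hashlib.sha1(blob).hexdigest()[:10]


@dataclass
class SimResult:
    """Everything produced by one simulated experiment."""

    config: RunConfig
    community13: CommunitySpec  # the labeled arm (ground truth)
    community12: CommunitySpec  # unlabeled control arm
    gradients: dict[str, SimulatedGradient]
    profiles: dict[str, list]  # isotope -> per-gradient qPCR profiles
    combined: dict[str, object]  # isotope -> duplicate-pooled profile
    pools: dict[str, PoolSpec]
    libraries: dict[str, LibraryTable]  # unamplified, keyed by pool label
    amplified: dict[str, LibraryTable]
    # taxa designated as substrate assimilators, independent of the applied
    # atom fraction (meaningful even when alpha13C is swept down to 0)
    labeled_taxon_ids: tuple[str, ...] = ()

    @property
    def labeled_genera(self) -> set[str]:
        by_id = {t.taxon_id: t for t in self.community13.taxa}
        return {by_id[tid].lineage[-1] for tid in self.labeled_taxon_ids}


def _expand_members(pool: PoolSpec, member_map: dict[int, list]) -> PoolSpec:
    """Map combined-profile fraction ranks back to source-gradient fractions."""
    members: list[tuple[str, int]] = []
    for _, idx in pool.member_fractions:
        members.extend(member_map[idx])
    return dataclasses.replace(pool, member_fractions=tuple(members))


def simulate_experiment(cfg: RunConfig) -> SimResult:
    """Run the generative arm: community, gradients, pools, 8 libraries."""
    model = cfg.density_model()
    sim = cfg.sim_config()
    community = make_community(
        cfg.n_taxa, cfg.n_labeled, seed=substream_seed(cfg.seed, "community"),
        class_mix=cfg.class_mix,
    )
    community13 = community.with_labeled_alpha(cfg.alpha13C)
    community12 = community.unlabeled()

    gradients: dict[str, SimulatedGradient] = {}
    profiles: dict[str, list] = {"12C": [], "13C": []}
    for isotope, comm in (("12C", community12), ("13C", community13)):
        for rep in range(1, cfg.n_gradients + 1):
            gid = f"{isotope}-G{rep}"
            grad = fractionate(comm, model, sim, gradient_id=gid, isotope=isotope)
            gradients[gid] = grad
            profiles[isotope].append(
                simulate_qpcr(grad, sim.qpcr_cv, seed=substream_seed(cfg.seed, f"qpcr:{gid}"))
            )
    comb12, map12 = combine_duplicates(profiles["12C"])
    comb13, map13 = combine_duplicates(profiles["13C"])
    pools = select_pools(comb12, comb13, min_mass=cfg.min_mass, heavy_cutoff=cfg.heavy_cutoff)
    pools = {
        label: _expand_members(pool, map12 if label.startswith("12C") else map13)
        for label, pool in pools.items()
    }
    libraries: dict[str, LibraryTable] = {}
    amplified: dict[str, LibraryTable] = {}
    for label, pool in pools.items():
        comm = community12 if label.startswith("12C") else community13
        lib = sample_reads(
            pool, gradients, comm, cfg.read_depth,
            seed=substream_seed(cfg.seed, f"reads:{label}"),
        )
        libraries[label] = lib
        amplified[label] = apply_amplification_bias(
            lib, sim.amp_kappa, seed=substream_seed(cfg.seed, f"amp:{label}")
        )
    logger.info(
        "simulated %d taxa (%d labeled at alpha=%.2f), %d libraries",
        cfg.n_taxa, cfg.n_labeled, cfg.alpha13C, len(libraries) + len(amplified),
    )
    return SimResult(
        config=cfg, community13=community13, community12=community12,
        gradients=gradients, profiles=profiles,
        combined={"12C": comb12, "13C": comb13},
        pools=pools, libraries=libraries, amplified=amplified,
        labeled_taxon_ids=tuple(t.taxon_id for t in community.taxa if t.alpha13C > 0),
    )


def analyze_libraries(result: SimResult) -> dict:
    """Run the analysis arm on a simulated experiment's libraries."""
    cfg = result.config
    all_tables = list(result.libraries.values()) + list(result.amplified.values())
    tallies = tally_frame(all_tables)
    gc_table = gc_frame(all_tables)

    ef_kwargs = dict(
        min_mean_abundance=cfg.min_mean_abundance,
        min_total_reads=cfg.min_total_reads,
        pseudo=cfg.pseudo,
    )
    ef = {
        "taxa_unamplified": ef_ranking(result.libraries, "taxon", cfg.taxon_level, **ef_kwargs),
        "taxa_amplified": ef_ranking(result.amplified, "taxon", cfg.taxon_level, **ef_kwargs),
        "transcripts_unamplified": ef_ranking(
            result.libraries, "transcript", cfg.transcript_level, **ef_kwargs
        ),
        "transcripts_amplified": ef_ranking(
            result.amplified, "transcript", cfg.transcript_level, **ef_kwargs
        ),
    }
    div_unamp, diffs_unamp = heavy_light_diversity(result.libraries)
    div_amp, diffs_amp = heavy_light_diversity(result.amplified)
    diversity_rows = [
        {"library_id": s.library_id, "shannon": s.shannon,
         "observed": s.observed_richness, "chao1": s.chao1}
        for s in list(div_unamp.values()) + list(div_amp.values())
    ]

    # paired amplified-vs-unamplified contrasts across the four pools
    pairs = {}
    for name, fn in (
        ("pct_nonrRNA", lambda t: 100.0 * (t.class_counts()["mRNA"] + t.class_counts()["other"]) / t.total_reads),
        ("mean_mrna_gc", lambda t: mean_gc_by_class(t, "mRNA")),
    ):
        diffs = [
            fn(result.amplified[lab]) - fn(result.libraries[lab]) for lab in POOL_LABELS
        ]
        t, df, p = paired_two_tailed_t(diffs)
        pairs[name] = {"mean_diff": float(np.mean(diffs)), "t": t, "df": df, "p": p}
    shannon_diffs = [
        div_amp[lab].shannon - div_unamp[lab].shannon for lab in POOL_LABELS
    ]
    t, df, p = paired_two_tailed_t(shannon_diffs)
    pairs["shannon"] = {"mean_diff": float(np.mean(shannon_diffs)), "t": t, "df": df, "p": p}

    # ground truth vs EF calls (confusion counts on the unamplified taxa table)
    taxa_table = ef["taxa_unamplified"]
    called = set(call_labeled(taxa_table, cfg.ef_call_threshold))
    truth = result.labeled_genera
    ranked = set(taxa_table["feature_id"]) if not taxa_table.empty else set()
    confusion = {
        "tp": len(called & truth),
        "fp": len(called - truth),
        "fn": len((ranked & truth) - called),
        "tn": len(ranked - truth - called),
        "n_ranked": len(ranked),
        "n_truth_ranked": len(ranked & truth),
    }
    return {
        "tallies": tallies,
        "gc": gc_table,
        "ef": ef,
        "diversity": pd.DataFrame(diversity_rows),
        "shannon_diffs": {"unamplified": diffs_unamp, "amplified": diffs_amp},
        "amplification_tests": pairs,
        "called_labeled": sorted(called),
        "labeled_truth": sorted(truth),
        "confusion": confusion,
    }


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        return [_jsonable(v) for v in sorted(obj)] if isinstance(obj, set) else [
            _jsonable(v) for v in obj
        ]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the full pipeline and write all stage TSVs plus a JSON summary.

    Deterministic given the config: re-running with the same configuration
    reproduces every output byte for byte. Returns the summary dict.
    """
    if cfg.out_dir is None:
        raise ValueError("RunConfig.out_dir must be set to run the pipeline")
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"config_hash": cfg.config_hash(), "seed": cfg.seed}

    stage = "simulate"
    try:
        result = simulate_experiment(cfg)
        sio.write_community_tsv(result.community13, out / "community.tsv", meta)
        sio.write_transcript_tsv(result.community13, out / "transcripts.tsv", meta)
        truth = {gid: g.fraction_total_mass() for gid, g in result.gradients.items()}
        all_profiles = result.profiles["12C"] + result.profiles["13C"]
        sio.write_fraction_tsv(all_profiles, out / "fractions.tsv", truth, meta)
        sio.write_masses_tsv(result.gradients, out / "masses.tsv", meta)
        sio.write_pool_tsv(result.pools, all_profiles, out / "pools.tsv", meta)
        sio.write_library_tsv(
            list(result.libraries.values()) + list(result.amplified.values()),
            out / "libraries.tsv", meta,
        )
        stage = "analyze"
        analysis = analyze_libraries(result)
        sio.write_tsv(analysis["tallies"], out / "class_tallies.tsv", meta)
        sio.write_tsv(analysis["gc"], out / "gc_by_class.tsv", meta)
        for name, frame in analysis["ef"].items():
            sio.write_tsv(frame.drop(columns=["lineage"]), out / f"ef_{name}.tsv", meta)
        sio.write_tsv(analysis["diversity"], out / "diversity.tsv", meta)
    except Exception as exc:
        raise type(exc)(f"[stage: {stage}] {exc}") from exc

    # out_dir is implied by the file location and excluded so that two runs
    # of one configuration are byte-identical wherever they are written
    portable_config = {k: v for k, v in cfg.to_dict().items() if k != "out_dir"}
    summary = {
        "config": portable_config,
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "pools": {
            label: {
                "density_window": list(p.density_window),
                "pooled_mass": p.pooled_mass,
                "member_fractions": [list(m) for m in p.member_fractions],
            }
            for label, p in result.pools.items()
        },
        "n_libraries": len(result.libraries) + len(result.amplified),
        "amplification_tests": analysis["amplification_tests"],
        "shannon_heavy_minus_light": analysis["shannon_diffs"],
        "labeled_truth": analysis["labeled_truth"],
        "called_labeled": analysis["called_labeled"],
        "confusion": analysis["confusion"],
    }
    with open(out / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(_jsonable(summary), fh, indent=2, sort_keys=True)
        fh.write("\n")
    (out / "config.json").write_text(
        json.dumps(_jsonable(portable_config), indent=2, sort_keys=True) + "\n",
        encoding="utf-8",
    )
    return summary


def simulate_and_rank(
    n_taxa: int = 20,
    n_labeled: int = 5,
    alpha: float = 1.0,
    depth: int = 100_000,
    seed: int = 1,
    *,
    min_mean_abundance: float = 0.0,
    **overrides,
) -> tuple[pd.DataFrame, SimResult]:
    """Convenience wrapper: one simulated experiment plus its genus-level EFs.

    ``min_mean_abundance`` defaults to 0 here (rank everything detected);
    pass 0.01 for the display-style filtered ranking. Returns the EF table
    of the unamplified libraries and the full simulation result.
    """
    cfg = RunConfig(
        n_taxa=n_taxa, n_labeled=n_labeled, alpha13C=alpha,
        read_depth=depth, seed=seed, **overrides,
    )
    result = simulate_experiment(cfg)
    ef = ef_ranking(
        result.libraries, "taxon", cfg.taxon_level,
        min_mean_abundance=min_mean_abundance,
        min_total_reads=cfg.min_total_reads, pseudo=cfg.pseudo,
    )
    return ef, result
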