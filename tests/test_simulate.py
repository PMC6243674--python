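"""Simulator: community construction, banding, fractionation, read sampling."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.stats import norm

from sipscope.errors import EmptyPoolError
from sipscope.gradients import PoolSpec
from sipscope.simulate import (
    CommunitySpec,
    DensityModel,
    SimConfig,
    apply_amplification_bias,
    fractionate,
    make_community,
    mean_density,
    sample_reads,
    simulate_qpcr,
)
from sipscope.tables import TAXON_RANKS


def _quiet_sim(**kw):
    return SimConfig(**kw)


class TestMakeCommunity:
    def test_single_taxon_normalizes_to_one(self):
        comm = make_community(n_taxa=1, n_labeled=0, seed=1)
        assert comm.taxa[0].rel_abundance == pytest.approx(1.0)
        assert comm.taxa[0].alpha13C == 0.0

    def test_construction_contract(self):
        comm = make_community(n_taxa=10, n_labeled=3, seed=7)
        assert sum(t.rel_abundance for t in comm.taxa) == pytest.approx(1.0, abs=1e-9)
        assert sum(t.alpha13C == 1.0 for t in comm.taxa) == 3
        assert all(t.alpha13C in (0.0, 1.0) for t in comm.taxa)
        for t in comm.taxa:
            assert len(t.lineage) == len(TAXON_RANKS)
            assert len(t.transcripts) >= 1
            assert sum(tr.expr_weight for tr in t.transcripts) == pytest.approx(1.0)

    def test_seed_determinism(self):
        assert make_community(10, 3, seed=7) == make_community(10, 3, seed=7)

    def test_genus_unique_per_taxon(self):
        comm = make_community(30, 5, seed=3)
        genera = [t.lineage[-1] for t in comm.taxa]
        assert len(set(genera)) == len(genera)

    def test_too_many_labeled_rejected(self):
        with pytest.raises(ValueError, match="n_labeled"):
            make_community(n_taxa=3, n_labeled=4, seed=0)


class TestMeanDensity:
    def test_unlabeled_reference_density(self):
        model = DensityModel()
        assert mean_density(model.gc_ref, 0.0, model) == pytest.approx(1.7785)

    def test_fully_labeled_density(self):
        model = DensityModel()
        assert mean_density(model.gc_ref, 1.0, model) == pytest.approx(1.8260)

    def test_half_labeling_is_exact_midpoint(self):
        model = DensityModel()
        lo = mean_density(model.gc_ref, 0.0, model)
        hi = mean_density(model.gc_ref, 1.0, model)
        assert mean_density(model.gc_ref, 0.5, model) == pytest.approx((lo + hi) / 2)

    def test_alpha_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            mean_density(55.0, 1.5)

    @given(
        gc=st.floats(20, 80),
        alpha=st.floats(0, 0.99),
        dgc=st.floats(0.1, 10),
        dalpha=st.floats(0.001, 0.01),
    )
    def test_strictly_increasing_in_alpha_and_gc(self, gc, alpha, dgc, dalpha):
        model = DensityModel()
        assert mean_density(gc, alpha + dalpha, model) > mean_density(gc, alpha, model)
        assert mean_density(gc + dgc, alpha, model) > mean_density(gc, alpha, model)


def _one_taxon_community(gc=55.0, alpha=0.0):
    comm = make_community(1, 0, seed=0)
    from dataclasses import replace

    taxon = replace(comm.taxa[0], gc_percent=gc, alpha13C=alpha)
    return CommunitySpec(taxa=(taxon,), class_mix=comm.class_mix)


class TestFractionate:
    def test_narrow_band_concentrates_in_one_fraction(self):
        # band centred mid-span with sigma far below the fraction width
        model = DensityModel(sigma=1e-4)
        cfg = _quiet_sim(n_fractions=7, gradient_span=(1.755, 1.845))
        mid = 0.5 * (1.755 + 1.845)
        alpha = (mid - model.rho0) / model.delta_max  # place the band mid-span
        comm = _one_taxon_community(gc=model.gc_ref, alpha=alpha)
        grad = fractionate(comm, model, cfg)
        masses = grad.masses.iloc[0]
        assert masses.max() / masses.sum() >= 0.99

    def test_boundary_centred_band_splits_evenly(self):
        model = DensityModel(sigma=5e-4)
        cfg = _quiet_sim(n_fractions=4, gradient_span=(1.76, 1.80))
        # interior boundary at 1.79 (= edges[1]); put the band mean exactly there
        alpha = (1.79 - model.rho0) / model.delta_max
        comm = _one_taxon_community(gc=model.gc_ref, alpha=alpha)
        grad = fractionate(comm, model, cfg)
        masses = grad.masses.iloc[0]
        assert masses[1] == pytest.approx(masses[2], rel=1e-9)
        assert masses[1] + masses[2] == pytest.approx(masses.sum(), rel=1e-6)

    def test_masses_match_quadrature_oracle(self):
        """Closed-form Gaussian integrals agree with brute-force quadrature."""
        model = DensityModel()
        cfg = _quiet_sim()
        comm = make_community(5, 2, seed=11)
        with pytest.warns(UserWarning):
            grad = fractionate(comm, model, cfg)
        low, high = cfg.gradient_span
        edges = np.linspace(high, low, cfg.n_fractions + 1)
        for taxon in comm.taxa:
            mu = mean_density(taxon.gc_percent, taxon.alpha13C, model)
            span_grid = np.linspace(low, high, 100_001)
            span_mass = np.trapezoid(norm.pdf(span_grid, mu, model.sigma), span_grid)
            for i in range(cfg.n_fractions):
                grid = np.linspace(edges[i + 1], edges[i], 10_000)
                oracle = np.trapezoid(norm.pdf(grid, mu, model.sigma), grid) / span_mass
                oracle *= taxon.rel_abundance * cfg.total_rna_ng
                assert grad.masses.loc[taxon.taxon_id, i + 1] == pytest.approx(
                    oracle, abs=1e-6 * cfg.total_rna_ng
                )

    @given(seed=st.integers(0, 50))
    def test_mass_conservation(self, seed):
        comm = make_community(8, 3, seed=seed)
        with pytest.warns(UserWarning):
            grad = fractionate(comm, DensityModel(), _quiet_sim())
        per_taxon = grad.masses.sum(axis=1)
        for taxon in comm.taxa:
            expected = taxon.rel_abundance * 1000.0
            assert per_taxon[taxon.taxon_id] == pytest.approx(expected, abs=1e-9 * 1000.0)

    def test_degenerate_span_rejected(self):
        with pytest.raises(ValueError):
            _quiet_sim(gradient_span=(1.8, 1.8))

    def test_fractions_ordered_heaviest_first(self):
        grad = fractionate(_one_taxon_community(), DensityModel(), _quiet_sim())
        densities = [grad.fraction_density(i + 1) for i in range(7)]
        assert densities == sorted(densities, reverse=True)


class TestSimulateQpcr:
    def test_zero_cv_returns_truth(self):
        grad = fractionate(_one_taxon_community(), DensityModel(), _quiet_sim())
        profile = simulate_qpcr(grad, cv=0.0, seed=5)
        truth = grad.fraction_total_mass()
        for f in profile.fractions:
            assert f.measured_copies == pytest.approx(truth[f.fraction_index])

    def test_noise_is_unbiased_in_the_mean(self):
        """Monte-Carlo oracle: lognormal multiplier has mean 1."""
        grad = fractionate(_one_taxon_community(), DensityModel(), _quiet_sim())
        truth = grad.fraction_total_mass().to_numpy()
        reps = np.stack(
            [
                np.array([f.measured_copies for f in
                          sorted(simulate_qpcr(grad, 0.2, seed=s).fractions,
                                 key=lambda f: f.fraction_index)])
                for s in range(1000)
            ]
        )
        keep = truth > 1.0  # fractions with appreciable mass
        ratio = reps.mean(axis=0)[keep] / truth[keep]
        assert np.all(np.abs(ratio - 1.0) < 0.02)

    def test_seed_determinism(self):
        grad = fractionate(_one_taxon_community(), DensityModel(), _quiet_sim())
        a = simulate_qpcr(grad, 0.3, seed=42)
        b = simulate_qpcr(grad, 0.3, seed=42)
        assert a == b


def _pool_all(grad):
    n = grad.masses.shape[1]
    return PoolSpec(
        pool_label="13C-heavy",
        density_window=(min(grad.edges), max(grad.edges)),
        member_fractions=tuple((grad.gradient_id, i + 1) for i in range(n)),
        pooled_mass=float(grad.masses.to_numpy().sum()),
    )


class TestSampleReads:
    def test_single_taxon_gets_all_rrna(self):
        comm = _one_taxon_community()
        grad = fractionate(comm, DensityModel(), _quiet_sim())
        lib = sample_reads(_pool_all(grad), {grad.gradient_id: grad}, comm, 5000, seed=1)
        ssu = lib.subset("SSU")
        assert set(ssu["feature_id"]) <= {comm.taxa[0].taxon_id}
        assert lib.total_reads == 5000

    def test_total_count_equals_depth(self):
        comm = make_community(6, 2, seed=2)
        with pytest.warns(UserWarning):
            grad = fractionate(comm, DensityModel(), _quiet_sim())
        lib = sample_reads(_pool_all(grad), {grad.gradient_id: grad}, comm, 12345, seed=9)
        assert lib.total_reads == 12345

    def test_counts_within_binomial_envelope(self):
        """Observed counts track expected proportions at the 4-sigma level."""
        comm = make_community(6, 2, seed=2)
        with pytest.warns(UserWarning):
            grad = fractionate(comm, DensityModel(), _quiet_sim())
        pool = _pool_all(grad)
        depth = 20_000
        mass = grad.masses.sum(axis=1)
        mix = comm.class_mix_dict
        # expected SSU proportion of the most abundant taxon
        top = mass.idxmax()
        p = float(mass[top] / mass.sum() * mix["SSU"])
        bound = 4 * np.sqrt(depth * p * (1 - p))
        hits = 0
        for seed in range(100):
            lib = sample_reads(pool, {grad.gradient_id: grad}, comm, depth, seed=seed)
            row = lib.data[(lib.data["feature_id"] == top) & (lib.data["class"] == "SSU")]
            count = int(row["count"].sum())
            hits += abs(count - depth * p) <= bound
        assert hits >= 99

    def test_empty_pool_rejected(self):
        comm = _one_taxon_community()
        grad = fractionate(comm, DensityModel(sigma=1e-4), _quiet_sim())
        empty = grad.masses.copy() * 0.0
        from dataclasses import replace

        zero_grad = replace(grad, masses=empty)
        with pytest.raises(EmptyPoolError):
            sample_reads(_pool_all(zero_grad), {grad.gradient_id: zero_grad}, comm, 100, seed=0)


class TestAmplificationBias:
    @staticmethod
    def _library(seed=4):
        comm = make_community(10, 3, seed=seed)
        with pytest.warns(UserWarning):
            grad = fractionate(comm, DensityModel(), _quiet_sim())
        return sample_reads(_pool_all(grad), {grad.gradient_id: grad}, comm, 50_000, seed=seed)

    def test_zero_kappa_leaves_counts_unchanged(self):
        lib = self._library()
        amp = apply_amplification_bias(lib, kappa=0.0, seed=1)
        pd.testing.assert_frame_equal(amp.data, lib.data)
        assert amp.amplified and amp.library_id.endswith("-amp")

    def test_expected_mrna_gc_decreases(self):
        """Reweighting oracle: the tilted expectation of mRNA GC drops, and
        resampled libraries track it."""
        lib = self._library()
        mrna = lib.subset("mRNA")
        gc = mrna["gc_percent"].to_numpy()
        n = mrna["count"].to_numpy().astype(float)
        kappa = 0.08
        w = n * np.exp(-kappa * (gc - 50.0))
        expected_gc = float(np.average(gc, weights=w))
        baseline_gc = float(np.average(gc, weights=n))
        assert expected_gc < baseline_gc
        resampled = [
            apply_amplification_bias(lib, kappa, seed=s) for s in range(30)
        ]
        means = []
        for amp in resampled:
            rows = amp.subset("mRNA")
            means.append(np.average(rows["gc_percent"], weights=rows["count"]))
        assert np.mean(means) == pytest.approx(expected_gc, abs=0.3)

    def test_rrna_rows_untouched(self):
        lib = self._library()
        amp = apply_amplification_bias(lib, kappa=0.2, seed=7)
        for cls in ("SSU", "LSU", "other"):
            pd.testing.assert_frame_equal(
                amp.subset(cls).reset_index(drop=True),
                lib.subset(cls).reset_index(drop=True),
            )

    def test_single_mrna_feature_invariant(self):
        rows = [
            ("t1", "taxon", "SSU", "p;c;o;f;g", 55.0, 90),
            ("k1", "transcript", "mRNA", "cat;path;k1", 60.0, 10),
        ]
        from conftest import make_library

        lib = make_library("L", "13C-heavy", rows)
        for kappa in (0.0, 0.1, 1.0):
            amp = apply_amplification_bias(lib, kappa, seed=3)
            assert int(amp.subset("mRNA")["count"].sum()) == 10

    def test_negative_kappa_rejected(self):
        with pytest.raises(ValueError):
            apply_amplification_bias(self._library(), kappa=-0.1, seed=0)
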