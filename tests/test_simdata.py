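"""Generative model: plasma proteome, affinities, adsorption, MS readout."""

import numpy as np
import pytest
from scipy import stats

from npcorona import (
    AffinitySpec,
    AssayDesign,
    NanoparticleModel,
    PlasmaProteome,
    apply_contamination,
    apply_spike,
    form_corona,
    generate_nanoparticles,
    generate_plasma_proteome,
    observe_ms,
    simulate_screen,
)

ONE_CONDITION = AssayDesign(conditions=("standard",))


class TestGeneratePlasmaProteome:
    def test_dynamic_range_is_exact(self):
        p = generate_plasma_proteome(5000, 10.0, seed=1)
        ratio = p.concentration.max() / p.concentration.min()
        assert ratio == pytest.approx(1e10, rel=1e-6)

    def test_seeded_determinism(self):
        a = generate_plasma_proteome(5000, 10.0, seed=1)
        b = generate_plasma_proteome(5000, 10.0, seed=1)
        np.testing.assert_array_equal(a.concentration, b.concentration)
        np.testing.assert_array_equal(a.is_platelet_signature, b.is_platelet_signature)
        assert {s: c.terms for s, c in a.annotations.items()} == \
               {s: c.terms for s, c in b.annotations.items()}

    def test_log_concentrations_uniform_over_span(self):
        p = generate_plasma_proteome(1000, 7.0, seed=7)
        logc = np.log10(p.concentration)
        assert logc.max() - logc.min() == pytest.approx(7.0)
        _, pvalue = stats.kstest(logc, stats.uniform(loc=logc.min(), scale=7.0).cdf)
        assert pvalue > 0.01

    @pytest.mark.parametrize("n,orders", [(1, 10.0), (5, -1.0), (5, 0.0)])
    def test_invalid_arguments_rejected(self, n, orders):
        with pytest.raises(ValueError):
            generate_plasma_proteome(n, orders, seed=0)


class TestGenerateNanoparticles:
    def test_top_affinity_sets_overlap_partially(self, small_proteome):
        models = generate_nanoparticles(small_proteome, 2, seed=3)
        tops = [
            frozenset(np.argsort(m.affinity)[-100:].tolist()) for m in models
        ]
        jaccard = len(tops[0] & tops[1]) / len(tops[0] | tops[1])
        assert 0.0 < jaccard < 1.0

    def test_zero_variance_spec_gives_identical_vectors(self, small_proteome):
        spec = AffinitySpec(log10_sd=0.0, n_bias_terms=0)
        models = generate_nanoparticles(small_proteome, 3, seed=3, affinity_spec=spec)
        for m in models[1:]:
            np.testing.assert_array_equal(m.affinity, models[0].affinity)

    def test_43_particles_have_unique_ids(self, small_proteome):
        models = generate_nanoparticles(small_proteome, 43, seed=1)
        assert len({m.np_id for m in models}) == 43

    def test_empty_proteome_rejected(self):
        empty = PlasmaProteome(np.array([], dtype=object), np.array([]))
        with pytest.raises(ValueError):
            generate_nanoparticles(empty, 2, seed=0)


class TestFormCorona:
    def test_saturation_limit_reaches_capacity(self):
        p = PlasmaProteome(np.array(["P1"], dtype=object), np.array([1e6]))
        m = NanoparticleModel("NP", affinity=np.array([1.0]), capacity=3.0)
        corona = form_corona(p, m)
        assert corona.bound_amount[0] == pytest.approx(3.0, rel=1e-5)

    def test_zero_affinity_binds_nothing(self, small_proteome):
        affinity = np.full(small_proteome.n_proteins, 1e-6)
        affinity[7] = 0.0
        m = NanoparticleModel("NP", affinity=affinity)
        assert form_corona(small_proteome, m).bound_amount[7] == 0.0

    def test_shared_denominator_preserves_ratios(self):
        p = PlasmaProteome(np.array(["P1", "P2"], dtype=object), np.array([9.0, 1.0]))
        m = NanoparticleModel("NP", affinity=np.array([2.0, 2.0]))
        b = form_corona(p, m).bound_amount
        assert b[0] / b[1] == 9.0

    def test_total_bound_never_exceeds_capacity(self, small_proteome, small_particles):
        for m in small_particles:
            corona = form_corona(small_proteome, m)
            assert corona.total_bound <= m.capacity

    def test_misaligned_affinity_rejected(self, small_proteome):
        m = NanoparticleModel("NP", affinity=np.ones(3))
        with pytest.raises(ValueError, match="length"):
            form_corona(small_proteome, m)


class TestObserveMs:
    def test_noiseless_unbounded_lod_reproduces_scaled_corona(self, small_proteome):
        m = NanoparticleModel("NP", np.full(small_proteome.n_proteins, 1e-6),
                              noise_cv=0.0, lod_mid=-np.inf)
        corona = form_corona(small_proteome, m)
        t = observe_ms(corona, m, ONE_CONDITION, seed=5, intensity_scale=1e9)
        arr = t.data.to_numpy()
        np.testing.assert_allclose(arr[:, 0], 1e9 * corona.bound_amount)
        np.testing.assert_array_equal(arr[:, 0], arr[:, 1])
        np.testing.assert_array_equal(arr[:, 0], arr[:, 2])

    def test_infinite_lod_mid_censors_everything(self, small_proteome):
        m = NanoparticleModel("NP", np.full(small_proteome.n_proteins, 1e-6),
                              lod_mid=np.inf)
        t = observe_ms(form_corona(small_proteome, m), m, ONE_CONDITION, seed=5)
        assert t.data.isna().all().all()

    @pytest.mark.parametrize("cv", [0.05, 0.22, 0.5])
    def test_median_replicate_cv_recovers_nominal(self, cv):
        # calibration contract: the median 3-replicate CV matches the dial
        p = generate_plasma_proteome(5000, 10.0, seed=2)
        m = NanoparticleModel("NP", np.full(p.n_proteins, 1e-6),
                              noise_cv=cv, lod_mid=-np.inf)
        t = observe_ms(form_corona(p, m), m, ONE_CONDITION, seed=6)
        vals = t.data.to_numpy()
        cvs = vals.std(axis=1, ddof=1) / vals.mean(axis=1)
        assert np.median(cvs) == pytest.approx(cv, rel=0.10)

    def test_screen_tsv_output_is_byte_identical_across_runs(
            self, small_proteome, small_particles, tmp_path):
        paths = []
        for name in ("a.tsv", "b.tsv"):
            t = simulate_screen(small_proteome, small_particles[:2], seed=9)
            t.write_tsv(tmp_path / name)
            paths.append(tmp_path / name)
        assert paths[0].read_bytes() == paths[1].read_bytes()


class TestApplySpike:
    def test_fold_series_multiplies_only_target(self):
        conc = np.array([4.11, 1.0, 250.0])
        p = PlasmaProteome(np.array(["CRP", "P1", "P2"], dtype=object), conc)
        series = apply_spike(p, "CRP", [1, 2, 5, 10, 100])
        got = [sp.concentration[0] for sp in series]
        assert got == pytest.approx([4.11, 8.22, 20.55, 41.1, 411.0])
        for sp in series:
            np.testing.assert_array_equal(sp.concentration[1:], conc[1:])

    def test_unit_fold_is_identity(self, small_proteome):
        (sp,) = apply_spike(small_proteome, small_proteome.protein_ids[0], [1.0])
        np.testing.assert_array_equal(sp.concentration, small_proteome.concentration)

    def test_zero_fold_rejected(self, small_proteome):
        with pytest.raises(ValueError):
            apply_spike(small_proteome, small_proteome.protein_ids[0], [0.0])

    def test_unknown_protein_rejected(self, small_proteome):
        with pytest.raises(KeyError):
            apply_spike(small_proteome, "NOPE", [2.0])


class TestApplyContamination:
    def test_lipid_leaves_protein_content_unchanged(self, small_proteome):
        out = apply_contamination(small_proteome, "lipid", 1000.0)
        np.testing.assert_array_equal(out.concentration, small_proteome.concentration)
        np.testing.assert_array_equal(out.protein_ids, small_proteome.protein_ids)

    def test_platelet_level_zero_is_identity(self, small_proteome):
        out = apply_contamination(small_proteome, "platelet", 0.0)
        np.testing.assert_array_equal(out.concentration, small_proteome.concentration)

    def test_platelet_scales_signature_only(self, small_proteome):
        out = apply_contamination(small_proteome, "platelet", 2.0)
        sig = small_proteome.is_platelet_signature
        np.testing.assert_allclose(out.concentration[sig],
                                   3.0 * small_proteome.concentration[sig])
        np.testing.assert_array_equal(out.concentration[~sig],
                                      small_proteome.concentration[~sig])

    def test_hemolysate_added_concentrations_scale_linearly(self, small_proteome):
        lo = apply_contamination(small_proteome, "hemolysate", 5.0)
        hi = apply_contamination(small_proteome, "hemolysate", 10.0)
        n0 = small_proteome.n_proteins
        assert lo.n_proteins > n0
        np.testing.assert_allclose(hi.concentration[n0:], 2.0 * lo.concentration[n0:])

    def test_unknown_mode_rejected(self, small_proteome):
        with pytest.raises(ValueError, match="mode"):
            apply_contamination(small_proteome, "dust", 1.0)
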