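"""Unit and property tests for the phantom simulator and its kinetics."""

import dataclasses

import numpy as np
import pytest

from dceauc.phantom import (
    PhantomSpec,
    PKParams,
    SequenceParams,
    add_noise,
    aif,
    build_phantom,
    concentration_to_r1,
    simulate_study,
    spgr_signal,
    tissue_pk,
)


def euler_oracle(cp, ktrans, ve, vp, kon, kd, bmax, t_grid, dt):
    """Independent fine-step explicit-Euler integration of the tissue model."""
    koff = kon * kd
    cf = cb = 0.0
    out = []
    t = 0.0
    for t_next in t_grid:
        n = max(1, int(round((t_next - t) / dt)))
        h = (t_next - t) / n if n else 0.0
        for _ in range(n):
            dcf = (ktrans / ve) * (cp(t) - cf) - kon * cf * (bmax - cb) + koff * cb
            dcb = kon * cf * (bmax - cb) - koff * cb
            cf += h * dcf
            cb += h * dcb
            t += h
        t = t_next
        out.append((cf, cb, vp * cp(t) + ve * cf + cb))
    return np.array(out)


class TestAif:
    def test_half_life(self):
        pk = PKParams(plasma_half_life=19.0)
        assert aif(19.0, pk) == pytest.approx(0.5 * aif(0.0, pk))
        assert aif(38.0, pk) == pytest.approx(0.25 * aif(0.0, pk))

    def test_initial_concentration_unit_consistent(self):
        # 10 µmol/kg into 100 mL/kg is 0.1 mM = 100 µM
        pk = PKParams(dose_per_kg=10.0, init_dist_volume=100.0)
        assert aif(0.0, pk) == pytest.approx(100.0)

    def test_monotone_nonincreasing(self):
        pk = PKParams()
        t = np.linspace(0, 120, 200)
        assert np.all(np.diff(aif(t, pk)) <= 0)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            aif(-1.0, PKParams())


class TestTissuePK:
    def test_no_binding_equilibrates_to_constant_input(self):
        cp = lambda t: np.full(np.shape(t), 5.0) if np.ndim(t) else 5.0  # noqa: E731
        cf, cb, _ = tissue_pk(cp, 0.3, 0.3, 0.05, 0.01, 1.8, 0.0, [200.0])
        assert cf[-1] == pytest.approx(5.0, rel=1e-6)
        assert np.all(cb == 0)

    def test_bound_steady_state_is_langmuir(self):
        # constant plasma input, long time: Cb -> Bmax*Cf/(kd + Cf)
        cp = lambda t: np.full(np.shape(t), 10.0) if np.ndim(t) else 10.0  # noqa: E731
        kon, kd, bmax = 0.05, 1.8, 30.0
        cf, cb, _ = tissue_pk(cp, 0.3, 0.3, 0.05, kon, kd, bmax, [3000.0])
        expected = bmax * cf[-1] / (kd + cf[-1])
        assert cb[-1] == pytest.approx(expected, rel=1e-3)

    @pytest.mark.parametrize("draw", range(4))
    def test_matches_fine_euler_oracle(self, draw):
        rng = np.random.default_rng(100 + draw)
        pk = PKParams()
        ktrans = rng.uniform(0.02, 0.4)
        ve = rng.uniform(0.1, 0.5)
        vp = rng.uniform(0.0, 0.15)
        kon = rng.uniform(0.001, 0.05)
        kd = rng.uniform(0.5, 200.0)
        bmax = rng.uniform(0.0, 60.0)
        cp = lambda t: aif(t, pk)  # noqa: E731
        t_grid = np.array([5.0, 20.0, 35.0, 45.0, 55.0, 80.0])
        cf, cb, ct = tissue_pk(cp, ktrans, ve, vp, kon, kd, bmax, t_grid, dt=0.1)
        ref = euler_oracle(cp, ktrans, ve, vp, kon, kd, bmax, t_grid, dt=0.001)
        rel = np.abs(ct - ref[:, 2]) / np.maximum(np.abs(ref[:, 2]), 1e-9)
        assert rel.max() < 1e-3

    def test_nonnegative_and_bounded_by_bmax(self):
        pk = PKParams()
        cp = lambda t: aif(t, pk)  # noqa: E731
        cf, cb, ct = tissue_pk(cp, 0.1, 0.2, 0.05, 0.01, 1.8, 20.0, np.linspace(1, 120, 60))
        assert np.all(cf >= 0) and np.all(cb >= 0) and np.all(ct >= 0)
        assert np.all(cb <= 20.0 + 1e-9)

    def test_total_concentration_nondecreasing_in_bmax(self):
        # binding monotonicity at 55 min for fixed delivery
        pk = PKParams()
        cp = lambda t: aif(t, pk)  # noqa: E731
        bmaxes = np.array([0.0, 5.0, 10.0, 20.0, 40.0])
        _, _, ct = tissue_pk(cp, 0.1, 0.2, 0.05, 0.0015, 1.8, bmaxes, [55.0])
        assert np.all(np.diff(ct[:, 0]) >= 0)

    def test_vectorized_matches_scalar(self):
        pk = PKParams()
        cp = lambda t: aif(t, pk)  # noqa: E731
        kt = np.array([0.05, 0.2])
        cf_v, cb_v, ct_v = tissue_pk(cp, kt, 0.2, 0.05, 0.002, 1.8, 10.0, [5.0, 55.0])
        for i, k in enumerate(kt):
            cf_s, cb_s, ct_s = tissue_pk(cp, float(k), 0.2, 0.05, 0.002, 1.8, 10.0, [5.0, 55.0])
            np.testing.assert_allclose(ct_v[i], ct_s, rtol=1e-12)

    def test_invalid_inputs_rejected(self):
        cp = lambda t: np.zeros(np.shape(t))  # noqa: E731
        with pytest.raises(ValueError):
            tissue_pk(cp, 0.1, 0.2, 0.05, 0.01, 1.8, 10.0, [5.0, 3.0])
        with pytest.raises(ValueError):
            tissue_pk(cp, 0.1, 0.2, 0.05, 0.01, 1.8, -1.0, [5.0])


class TestRelaxivityAndSignal:
    def test_linear_relaxivity(self):
        # 100 µM at 16.2 mM⁻¹s⁻¹ adds 1.62 s⁻¹
        assert concentration_to_r1(100.0, 16.2, 0.5) == pytest.approx(2.12)
        assert concentration_to_r1(0.0, 16.2, 0.5) == pytest.approx(0.5)
        d1 = concentration_to_r1(50.0, 16.2, 0.5) - 0.5
        d2 = concentration_to_r1(100.0, 16.2, 0.5) - 0.5
        assert d2 == pytest.approx(2 * d1)
        with pytest.raises(ValueError):
            concentration_to_r1(-1.0, 16.2, 0.5)

    def test_spgr_closed_form(self):
        seq = SequenceParams(tr=92.6, flip=35.0)
        # independent direct evaluation of the steady-state expression
        e = np.exp(-0.0926 * 1.0)
        expected = 1.0 * np.sin(np.radians(35.0)) * (1 - e) / (1 - e * np.cos(np.radians(35.0)))
        assert spgr_signal(1.0, seq, 1.0) == pytest.approx(expected, abs=1e-12)

    def test_spgr_limits(self):
        seq = SequenceParams(tr=92.6, flip=35.0)
        assert spgr_signal(1e6, seq, 2.0) == pytest.approx(2.0 * np.sin(np.radians(35.0)))
        seq90 = SequenceParams(flip=90.0)
        e = np.exp(-0.0926 * 0.8)
        assert spgr_signal(0.8, seq90, 1.0) == pytest.approx(1 - e)

    def test_spgr_increasing_in_r1(self):
        seq = SequenceParams()
        r1 = np.linspace(0.1, 5.0, 50)
        assert np.all(np.diff(spgr_signal(r1, seq, 1.0)) > 0)

    def test_spgr_invalid(self):
        with pytest.raises(ValueError):
            spgr_signal(0.0, SequenceParams(), 1.0)
        with pytest.raises(ValueError):
            SequenceParams(tr=-1.0)


class TestNoise:
    def test_zero_sigma_identity(self):
        v = np.arange(12.0).reshape(3, 4)
        out = add_noise(v, 0.0, seed=1)
        np.testing.assert_array_equal(out, v)

    def test_rayleigh_mean_on_zero_signal(self):
        # magnitude of pure noise has mean sigma*sqrt(pi/2)
        sigma, n = 2.0, 100_000
        out = add_noise(np.zeros(n), sigma, seed=7)
        expected = sigma * np.sqrt(np.pi / 2)
        se = sigma * np.sqrt(2 - np.pi / 2) / np.sqrt(n)
        assert abs(out.mean() - expected) < 3 * se

    def test_seed_determinism_and_nonnegativity(self):
        v = np.random.default_rng(0).uniform(0, 5, (4, 4))
        a = add_noise(v, 0.5, seed=3)
        b = add_noise(v, 0.5, seed=3)
        np.testing.assert_array_equal(a, b)
        assert np.all(a >= 0)
        with pytest.raises(ValueError):
            add_noise(v, -0.1, seed=0)


class TestPKParams:
    def test_derived_quantities(self):
        pk = PKParams()
        assert pk.koff == pytest.approx(pk.kon * pk.kd)
        assert pk.r1_per_gd == pytest.approx(16.2 / 3)
        assert pk.injection_volume_ul_per_g == pytest.approx(2.0)

    def test_control_pair_affinity(self):
        pk = PKParams()
        ctl = pk.control()
        assert ctl.kd >= 100 * pk.kd
        assert ctl.r1_molecular == pk.r1_molecular
        with pytest.raises(ValueError):
            pk.control(affinity_loss=10.0)

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            PKParams(kd=-1.0)
        with pytest.raises(ValueError):
            PKParams(ve=0.0)
        with pytest.raises(ValueError):
            PKParams(vp=1.0)


class TestBuildPhantom:
    def test_collagen_fold_change_and_class_means(self):
        spec = PhantomSpec(seed=5)
        truth, rois = build_phantom(spec)
        means = {}
        # the field is smoothed, so the effective sample size is the voxel
        # count divided by the kernel's correlation volume (2σ√π)³
        corr_vol = (2 * spec.smooth_sigma * np.sqrt(np.pi)) ** 3
        for name, lab in {"tumour": 1, "pancreas": 3}.items():
            m = truth.class_map == lab
            cls = spec.classes[name]
            sem = cls.hyp_sd / np.sqrt(m.sum() / corr_vol)
            assert abs(truth.hyp_map[m].mean() - cls.hyp_mean) < 3 * sem + 1e-9
            means[name] = truth.hyp_map[m].mean()
        assert means["tumour"] / means["pancreas"] == pytest.approx(1224 / 523, rel=0.05)

    def test_labels_partition_and_rois_disjoint(self):
        truth, rois = build_phantom(PhantomSpec(seed=2))
        assert set(np.unique(truth.class_map)) <= {0, 1, 2, 3, 4}
        tum, mus = rois.mask("tumour"), rois.mask("muscle")
        assert tum.any() and mus.any()
        assert not np.any(tum & mus)
        # Bmax is the fixed linear function of collagen
        np.testing.assert_allclose(truth.bmax_map, 0.025 * truth.hyp_map, rtol=1e-12)

    def test_zero_heterogeneity_gives_constant_classes(self):
        spec = PhantomSpec(seed=3)
        spec.classes = {
            name: dataclasses.replace(c, hyp_sd=0.0, ktrans_sd_log=0.0)
            for name, c in spec.classes.items()
        }
        truth, _ = build_phantom(spec)
        for lab in (1, 2, 3, 4):
            m = truth.class_map == lab
            assert np.ptp(truth.hyp_map[m]) == 0
            assert np.ptp(truth.ktrans_map[m]) < 1e-12

    def test_seed_reproducible(self):
        a, _ = build_phantom(PhantomSpec(seed=9))
        b, _ = build_phantom(PhantomSpec(seed=9))
        np.testing.assert_array_equal(a.hyp_map, b.hyp_map)
        np.testing.assert_array_equal(a.ktrans_map, b.ktrans_map)

    def test_empty_class_geometry_rejected(self):
        with pytest.raises(ValueError):
            build_phantom(PhantomSpec(tumour_radii=(0.1, 0.1, 0.1), seed=0))

    def test_necrotic_must_be_low_collagen(self):
        spec = PhantomSpec()
        spec.classes = dict(spec.classes)
        spec.classes["necrotic"] = dataclasses.replace(
            spec.classes["necrotic"], hyp_mean=2000.0
        )
        with pytest.raises(ValueError):
            PhantomSpec(classes=spec.classes)


@pytest.fixture(scope="module")
def tiny_spec():
    return PhantomSpec(
        shape=(24, 24, 4),
        tumour_center=(8.0, 13.0, 1.5),
        tumour_radii=(5.0, 5.0, 1.4),
        necrotic_radii=(2.0, 2.0, 0.7),
        pancreas_center=(18.0, 13.0, 1.5),
        pancreas_radii=(3.5, 3.5, 1.2),
        muscle_rows=3,
        seed=11,
    )


class TestSimulateStudy:
    def test_one_volume_per_time_and_clean_baseline(self, tiny_spec):
        series, rois, truth = simulate_study(tiny_spec, probe="targeted")
        assert series.data.shape[3] == len(SequenceParams().sample_times)
        assert np.all(truth.conc_curves[..., 0] == 0)

    def test_noiseless_determinism(self, tiny_spec):
        spec = dataclasses.replace(tiny_spec, noise_sigma=0.0)
        s1, _, _ = simulate_study(spec, probe="targeted")
        s2, _, _ = simulate_study(spec, probe="targeted")
        np.testing.assert_array_equal(s1.data, s2.data)

    def test_targeted_retains_control_washes_out(self, tiny_spec):
        spec = dataclasses.replace(tiny_spec, noise_sigma=0.0)
        _, rois, t_tgt = simulate_study(spec, probe="targeted")
        _, _, t_ctl = simulate_study(spec, probe="control")
        tum = rois.mask("tumour")
        tgt = t_tgt.conc_curves[tum].mean(axis=0)  # noiseless mean tumour Ct
        ctl = t_ctl.conc_curves[tum].mean(axis=0)
        times = t_tgt.conc_times
        i5, i35 = list(times).index(5.0), list(times).index(35.0)
        assert tgt[i35] > tgt[i5]
        assert np.all(np.diff(ctl[i5:]) < 0)

    def test_gd_table_ordering(self, tiny_spec):
        _, _, t_tgt = simulate_study(tiny_spec, probe="targeted")
        _, _, t_ctl = simulate_study(tiny_spec, probe="control")
        gd = lambda t, tis: float(  # noqa: E731
            t.specimen_table.set_index("tissue").loc[tis, "sim_gd_nmol_g"]
        )
        assert gd(t_tgt, "tumour") > gd(t_ctl, "tumour")
        assert gd(t_tgt, "tumour") > gd(t_tgt, "pancreas")

    def test_bad_probe_rejected(self, tiny_spec):
        with pytest.raises(ValueError):
            simulate_study(tiny_spec, probe="other")
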