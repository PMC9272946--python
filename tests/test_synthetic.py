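import numpy as np
import pytest

from dividemri import (
    MicroTensor,
    TensorDistribution,
    add_rician_noise,
    build_protocol,
    dtd_moments,
    make_phantom,
    powder_signal,
    simulate_signal,
)
from dividemri.synthetic import PhantomSpec, phantom_rois, sphere_points

from conftest import random_dtd


def cumulant_variance(dtd, b_delta):
    """Independent numeric oracle: fit ln S on a fine low-b grid of exactly
    powder-averaged signals; the quadratic coefficient is half the variance
    of the apparent diffusivity distribution."""
    b = np.linspace(0.0, 0.1, 41)
    s = powder_signal(dtd, b, b_delta)
    coef = np.polynomial.polynomial.polyfit(b, np.log(s), 6)
    return -coef[1], 2.0 * coef[2]  # (MD, V)


class TestSimulateSignal:
    def test_single_isotropic_is_monoexponential(self, study_scheme):
        dtd = TensorDistribution.isotropic_mixture([1.0])
        s = simulate_signal(dtd, study_scheme, s0=1.0)
        assert np.allclose(s, np.exp(-study_scheme.b))

    def test_ste_shell_identical_across_directions(self, rng, study_scheme):
        dtd = random_dtd(rng)
        s = simulate_signal(dtd, study_scheme, s0=1.0)
        for b, bd, idx in study_scheme.shells():
            if bd == 0.0:
                assert np.ptp(s[idx]) == 0.0

    def test_mixture_linearity(self):
        scheme = build_protocol([1.0], shapes=(0.0,), n_directions=1)
        dtd = TensorDistribution.isotropic_mixture([0.5, 1.5])
        s = simulate_signal(dtd, scheme, s0=2.0)
        assert s[0] == pytest.approx((np.exp(-0.5) + np.exp(-1.5)))

    def test_positive_and_b0_normalized(self, rng):
        scheme = build_protocol([0.0, 0.5, 1.5], shapes=(1.0, 0.0), n_directions=4)
        for _ in range(10):
            dtd = random_dtd(rng)
            s = simulate_signal(dtd, scheme, s0=3.0)
            assert np.all(s > 0) and np.all(s <= 3.0 + 1e-12)
            assert np.allclose(s[scheme.b == 0], 3.0)

    def test_monotone_in_b_within_shape_and_direction(self, rng):
        n = np.array([0.0, 0.0, 1.0])
        from dividemri import EncodingEntry, EncodingScheme

        bs = [0.1, 0.4, 0.9, 1.5]
        scheme = EncodingScheme([EncodingEntry(b, 1.0, n) for b in bs])
        for _ in range(5):
            s = simulate_signal(random_dtd(rng), scheme)
            assert np.all(np.diff(s) < 0)

    def test_empty_distribution_rejected(self):
        with pytest.raises(ValueError):
            TensorDistribution([])

    def test_invalid_s0_rejected(self, study_scheme):
        with pytest.raises(ValueError):
            simulate_signal(TensorDistribution.isotropic_mixture([1.0]), study_scheme, s0=0.0)


class TestMoments:
    def test_single_isotropic_component_zero_kurtosis(self):
        gt = dtd_moments(TensorDistribution.isotropic_mixture([1.3]))
        assert gt.md == pytest.approx(1.3)
        assert gt.mk_i == 0.0 and gt.mk_a == 0.0

    def test_two_point_isotropic_mixture(self):
        gt = dtd_moments(TensorDistribution.isotropic_mixture([0.5, 1.5]))
        assert gt.md == pytest.approx(1.0)
        assert gt.mk_i == pytest.approx(0.75)
        assert gt.mk_a == pytest.approx(0.0)

    def test_randomly_oriented_stick_like_tensor(self):
        dtd = TensorDistribution.randomly_oriented(2.1, 0.1, n_orientations=64)
        gt = dtd_moments(dtd)
        assert gt.md == pytest.approx((2.1 + 0.2) / 3.0)
        # V_A = (4/45) * (2.1-0.1)^2 = 0.35556; MK_A = 3 V_A / MD^2
        assert gt.mk_a == pytest.approx(3 * (4 / 45) * 4.0 / gt.md**2, rel=1e-9)
        assert gt.mk_i == pytest.approx(0.0, abs=1e-12)

    def test_zero_md_distribution_has_zero_kurtosis(self):
        # non-negative eigenvalues force zero variance when MD = 0, so the
        # degenerate case is well-defined rather than an error
        gt = dtd_moments(TensorDistribution([(1.0, MicroTensor(0.0, 0.0))]))
        assert gt.md == 0.0 and gt.mk_i == 0.0 and gt.mk_a == 0.0

    def test_agrees_with_cumulant_oracle(self, rng):
        """Moment formulas vs numeric low-b cumulant fit: V_STE = Var(Diso),
        V_LTE - V_STE = (4/45) sum f (lpar - lperp)^2, on 20 random dtds."""
        for _ in range(20):
            dtd = random_dtd(rng)
            gt = dtd_moments(dtd)
            var_iso = gt.mk_i * gt.md**2 / 3.0
            v_a = gt.mk_a * gt.md**2 / 3.0
            md_ste, v_ste = cumulant_variance(dtd, 0.0)
            md_lte, v_lte = cumulant_variance(dtd, 1.0)
            assert md_ste == pytest.approx(gt.md, rel=1e-6)
            assert md_lte == pytest.approx(gt.md, rel=1e-6)
            assert v_ste == pytest.approx(var_iso, rel=1e-6, abs=1e-9)
            assert v_lte - v_ste == pytest.approx(v_a, rel=1e-6, abs=1e-9)

    def test_from_moment_targets_hits_targets(self, rng):
        for _ in range(10):
            md = rng.uniform(0.6, 1.8)
            mk_i = rng.uniform(0.1, 1.4)
            mk_a = rng.uniform(0.1, 1.0)
            dtd = TensorDistribution.from_moment_targets(md, mk_i, mk_a, rng=rng)
            gt = dtd_moments(dtd)
            assert gt.md == pytest.approx(md, rel=0.02)
            assert gt.mk_i == pytest.approx(mk_i, rel=0.05)
            assert gt.mk_a == pytest.approx(mk_a, rel=0.02)


class TestShapeSeparationMechanism:
    def test_ste_depends_only_on_diso_distribution(self, study_scheme):
        """Two dtds with the same isotropic-diffusivity distribution but very
        different anisotropy give identical spherical-encoding signals."""
        aniso = TensorDistribution.randomly_oriented(2.5, 0.25, n_orientations=32)
        diso = dtd_moments(aniso).md
        iso = TensorDistribution.isotropic_mixture([diso])
        s_a = simulate_signal(aniso, study_scheme)
        s_i = simulate_signal(iso, study_scheme)
        ste = study_scheme.b_delta == 0.0
        assert np.allclose(s_a[ste], s_i[ste], rtol=1e-12)
        assert not np.allclose(s_a[~ste], s_i[~ste])

    def test_lte_above_ste_at_high_b_for_microscopic_anisotropy(self):
        """Powder-averaged linear- and spherical-encoding curves coincide at
        b -> 0 and diverge at high b, linear above spherical."""
        dtd = TensorDistribution.randomly_oriented(2.0, 0.2, n_orientations=128)
        b = np.linspace(0.0, 1.5, 16)
        s_lte = powder_signal(dtd, b, 1.0)
        s_ste = powder_signal(dtd, b, 0.0)
        assert s_lte[0] == pytest.approx(s_ste[0])
        assert s_lte[1] - s_ste[1] < s_lte[-1] - s_ste[-1]
        assert s_lte[-1] > s_ste[-1] * 1.05

    def test_isotropic_heterogeneity_curves_overlap(self):
        dtd = TensorDistribution.isotropic_mixture([0.4, 1.6])
        b = np.linspace(0.0, 1.5, 6)
        assert np.allclose(powder_signal(dtd, b, 1.0), powder_signal(dtd, b, 0.0), rtol=1e-12)


class TestRicianNoise:
    def test_sigma_zero_is_identity(self):
        s = np.array([1.0, 0.5, 0.2])
        out = add_rician_noise(s, 0.0, rng=0)
        assert np.array_equal(out, s)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            add_rician_noise(np.ones(3), -1.0)

    def test_rayleigh_floor_mean(self):
        out = add_rician_noise(np.zeros(200_000), 1.0, rng=7)
        assert out.mean() == pytest.approx(np.sqrt(np.pi / 2), rel=0.01)

    def test_seed_reproducible(self):
        s = np.linspace(0, 1, 50)
        assert np.array_equal(add_rician_noise(s, 0.3, rng=11), add_rician_noise(s, 0.3, rng=11))


class TestPhantom:
    def test_fixed_seed_bit_identical(self, study_scheme):
        spec = PhantomSpec(shape=(4, 8, 1), seed=3, n_orientations=32)
        a = make_phantom(spec, study_scheme)
        b = make_phantom(PhantomSpec(shape=(4, 8, 1), seed=3, n_orientations=32), study_scheme)
        assert np.array_equal(a.signal, b.signal)
        assert np.array_equal(a.truth["md"], b.truth["md"], equal_nan=True)

    def test_single_voxel_noise_free_recovers_oracle(self, study_scheme):
        from dividemri import fit_gamma, powder_average

        spec = PhantomSpec(shape=(1, 4, 1), seed=5, sigma_rel=0.0, n_orientations=64)
        ph = make_phantom(spec, study_scheme)
        vox = np.argwhere(ph.labels > 0)[0]
        sig = ph.signal[tuple(vox)]
        res = fit_gamma(powder_average(sig, study_scheme))
        truth = {k: ph.truth[k][tuple(vox)] for k in ("md", "mk_i", "mk_a")}
        # gamma-model approximation error on multi-Gaussian data, noise-free
        assert res.md == pytest.approx(truth["md"], rel=0.05)
        assert res.mk_i == pytest.approx(truth["mk_i"], abs=0.15)
        assert res.mk_a == pytest.approx(truth["mk_a"], abs=0.25)

    def test_ground_truth_class_orderings(self, study_scheme):
        spec = PhantomSpec(seed=2, n_orientations=16)
        ph = make_phantom(spec, study_scheme)
        med = {
            name: {k: np.nanmedian(ph.truth[k][ph.labels == code]) for k in ("md", "mk_i", "mk_a")}
            for code, name in [(1, "tumor"), (2, "PZ"), (3, "TZ")]
        }
        assert med["tumor"]["md"] < min(med["PZ"]["md"], med["TZ"]["md"])
        assert med["tumor"]["mk_i"] > max(med["PZ"]["mk_i"], med["TZ"]["mk_i"])
        assert med["PZ"]["md"] < med["TZ"]["md"]
        assert med["PZ"]["mk_a"] > med["TZ"]["mk_a"]

    def test_unknown_label_rejected(self):
        labels = np.full((2, 2, 1), 9)
        with pytest.raises(ValueError, match="unknown class"):
            PhantomSpec(shape=(2, 2, 1), labels=labels)

    def test_roi_split_covers_classes(self):
        spec = PhantomSpec(seed=0)
        rois, label_map = phantom_rois(spec.labels)
        assert set(label_map.values()) == {"G3+3", "G3+4", "G4+3", "PZ", "TZ"}
        assert np.all((rois > 0) == (spec.labels > 0))

    def test_write_outputs(self, tmp_path, study_scheme):
        import nibabel as nib

        spec = PhantomSpec(shape=(2, 4, 1), seed=1, n_orientations=8)
        ph = make_phantom(spec, study_scheme)
        ph.write(tmp_path, study_scheme)
        img = nib.load(tmp_path / "signal.nii")
        assert img.shape == (2, 4, 1, 80)
        assert (tmp_path / "labels.json").exists()
        assert (tmp_path / "scheme.txt").exists()


class TestSpherePoints:
    def test_quasi_uniform_moments(self):
        p = sphere_points(512)
        assert np.allclose(p.mean(axis=0), 0.0, atol=0.05)
        # second moment of uniform sphere: E[x x^T] = I/3
        assert np.allclose(p.T @ p / len(p), np.eye(3) / 3, atol=0.01)

    def test_randomly_oriented_copy_count_convergence(self):
        """Orientation expansion converges: MK_A from discrete copies matches
        the analytic single-tensor value for increasing copy counts."""
        exact = 3 * (4 / 45) * (2.0 - 0.2) ** 2 / ((2.0 + 0.4) / 3) ** 2
        for n in (64, 256):
            gt = dtd_moments(TensorDistribution.randomly_oriented(2.0, 0.2, n))
            assert gt.mk_a == pytest.approx(exact, rel=1e-9)
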