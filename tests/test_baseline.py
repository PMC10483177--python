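import numpy as np
import pytest

from chromaplot import Curve, SynthSpec, fit_baseline_als, subtract_baseline, synth_chromatogram
from chromaplot.baseline import CORRECTED_SUFFIX, default_lambda
from _oracles import dense_als


def smooth_random_curve(rng, n):
    x = np.linspace(0, 10, n)
    y = (
        rng.uniform(0, 5)
        + rng.uniform(-0.3, 0.3) * x
        + rng.uniform(10, 80) * np.exp(-0.5 * ((x - rng.uniform(3, 7)) / 0.8) ** 2)
        + rng.normal(0, 0.4, n)
    )
    return Curve("UV 1_280", x, y)


class TestAlsFit:
    def test_constant_curve_is_its_own_baseline(self):
        c = Curve("flat", np.linspace(0, 1, 50), np.full(50, 7.5))
        for lam, p in [(1e2, 0.5), (1e6, 0.01)]:
            m = fit_baseline_als(c, lam, p)
            assert np.allclose(m.z, 7.5, atol=1e-9)

    def test_vanishing_penalty_interpolates_the_data(self):
        rng = np.random.default_rng(0)
        c = smooth_random_curve(rng, 80)
        m = fit_baseline_als(c, lambda_smooth=1e-12, p_asymmetry=0.5)
        assert np.max(np.abs(m.z - c.y)) < 1e-6

    def test_sparse_fit_matches_dense_penalized_wls_oracle(self):
        """The sparse pentadiagonal solve and a brute-force dense WLS give
        the same baseline to 1e-8 over a (lambda, p) grid."""
        rng = np.random.default_rng(11)
        for n in (50, 120, 200):
            c = smooth_random_curve(rng, n)
            for lam in (1e2, 1e4, 1e6):
                for p in (0.01, 0.1, 0.5):
                    m = fit_baseline_als(c, lam, p)
                    z_ref = dense_als(c.y, lam, p)
                    assert np.max(np.abs(m.z - z_ref)) < 1e-8, (n, lam, p)

    def test_recovers_linear_drift_under_three_peaks(self):
        spec = SynthSpec(
            peaks=((10.0, 80.0, 0.3), (14.0, 120.0, 0.35), (17.5, 40.0, 0.25)),
            drift=(2.0, 0.15),
            noise_sd=0.5,
            seed=7,
        )
        chrom, truth = synth_chromatogram(spec)
        c = chrom.curves[0]
        m = fit_baseline_als(c)
        peak_free = np.ones(len(c), bool)
        for center, _, sigma in spec.peaks:
            peak_free &= np.abs(c.x - center) > 4 * sigma
        err = np.median(np.abs(m.z - truth.drift_values)[peak_free])
        assert err < 1.0
        assert m.converged

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_baseline_stays_below_peaks_with_small_p(self, seed):
        """The asymmetry weight controls how far into the noise the baseline
        sinks: at p = 0.001 no more than 5% of samples lie below it on
        peak-dominated traces."""
        spec = SynthSpec(
            peaks=((10.0, 80.0, 0.3), (14.0, 120.0, 0.35), (17.5, 40.0, 0.25)),
            noise_sd=0.5,
            seed=seed,
            n_fractions=0,
        )
        chrom, _ = synth_chromatogram(spec)
        c = chrom.curves[0]
        m = fit_baseline_als(c, p_asymmetry=0.001)
        assert np.mean(m.z > c.y) <= 0.05

    def test_fit_is_deterministic(self):
        rng = np.random.default_rng(9)
        c = smooth_random_curve(rng, 150)
        z1 = fit_baseline_als(c).z
        z2 = fit_baseline_als(c).z
        assert np.array_equal(z1, z2)

    def test_too_short_curve_rejected(self):
        with pytest.raises(ValueError, match="3 points"):
            fit_baseline_als(Curve("c", [0.0, 1.0], [0.0, 1.0]))

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"lambda_smooth": 0.0},
            {"p_asymmetry": 0.0},
            {"p_asymmetry": 1.0},
            {"max_iter": 0},
            {"tol": 0.0},
        ],
    )
    def test_parameter_domains_enforced(self, kwargs):
        c = Curve("c", [0.0, 1.0, 2.0], [0.0, 1.0, 0.0])
        with pytest.raises(ValueError):
            fit_baseline_als(c, **kwargs)

    def test_default_lambda_matches_convention_at_typical_export_size(self):
        # ~600-point exports get the classic 1e6 stiffness
        assert default_lambda(632) == pytest.approx(1e6, rel=0.02)


class TestSubtract:
    def test_constant_curve_corrects_to_zero(self):
        c = Curve("flat", np.linspace(0, 1, 30), np.full(30, 4.0))
        corrected = subtract_baseline(c, fit_baseline_als(c))
        assert np.allclose(corrected.y, 0.0, atol=1e-9)
        assert corrected.name == "flat" + CORRECTED_SUFFIX

    def test_mismatched_model_rejected(self):
        c1 = Curve("a", [0.0, 1.0, 2.0], [0.0, 1.0, 0.0])
        c2 = Curve("b", [0.0, 1.0, 2.0], [0.0, 1.0, 0.0])
        with pytest.raises(ValueError):
            subtract_baseline(c2, fit_baseline_als(c1))
        short = Curve("a", [0.0, 1.0], [0.0, 1.0])
        with pytest.raises(ValueError):
            subtract_baseline(short, fit_baseline_als(c1))

    def test_refit_after_subtraction_is_near_zero_off_peak(self):
        spec = SynthSpec(
            peaks=((14.0, 120.0, 0.35),), drift=(2.0, 0.15), noise_sd=0.5, seed=1
        )
        chrom, _ = synth_chromatogram(spec)
        c = chrom.curves[0]
        m = fit_baseline_als(c)
        corrected = subtract_baseline(c, m)
        m2 = fit_baseline_als(corrected)
        off_peak = np.abs(c.x - 14.0) > 4 * 0.35
        assert np.median(np.abs(m2.z[off_peak])) < 2 * spec.noise_sd
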