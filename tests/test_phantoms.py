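import numpy as np
import pytest

from fiborient import (
    ConfigError,
    EmptyPDFError,
    FiberFamily,
    PhantomSpec,
    analyze_image,
    build_pdf,
    compute_gradient,
    fit_gaussians,
    make_dark_count_image,
    make_fiber_image,
    make_noise_image,
    normalize_image,
    sample_orientation_pdf,
    threshold_from_fraction,
)


def dominant_bin_center(img, R=1, B=5, t_fraction=0.1):
    field = compute_gradient(img, R)
    pdf = build_pdf(field, threshold_from_fraction(field, t_fraction), B)
    return pdf.bin_centers[int(np.argmax(pdf.density))]


class TestSpecValidation:
    def test_family_count_bounds(self):
        fams = tuple({"orientation": 10.0 * i} for i in range(4))
        with pytest.raises(ConfigError):
            PhantomSpec(families=fams)
        with pytest.raises(ConfigError):
            PhantomSpec(families=())

    @pytest.mark.parametrize(
        "kwargs",
        [{"period": 1.0}, {"amplitude": -1.0}, {"waviness": 95.0}],
    )
    def test_family_field_bounds(self, kwargs):
        with pytest.raises(ConfigError):
            FiberFamily(orientation=0.0, **kwargs)

    def test_json_roundtrip(self, tmp_path):
        spec = PhantomSpec(
            families=({"orientation": 30.0, "waviness": 5.0},),
            noise_model={"kind": "poisson", "peak": 20},
            mixing="additive",
            seed=9,
        )
        p = tmp_path / "spec.json"
        spec.to_json(p)
        assert PhantomSpec.from_json(p) == spec


class TestFiberImage:
    def test_deterministic_for_identical_spec(self):
        spec = PhantomSpec(
            families=({"orientation": 30.0},),
            noise_model={"kind": "poisson", "peak": 15},
            seed=3,
        )
        a = make_fiber_image(spec)
        b = make_fiber_image(spec)
        np.testing.assert_array_equal(a.pixels, b.pixels)

    def test_gradients_perpendicular_to_fibers(self, grating45):
        # fibers at 45 degrees -> gradient orientation 135
        center = dominant_bin_center(grating45)
        assert abs(center - 135.0) <= 2.5  # 135 inside the dominant bin

    def test_background_only_phantom_has_no_gradients(self):
        spec = PhantomSpec(
            families=({"orientation": 45.0, "amplitude": 0.0},),
            background=0.5,
            seed=0,
        )
        img = make_fiber_image(spec)
        field = compute_gradient(img, 1)
        assert not field.valid_mask.any()
        with pytest.raises(EmptyPDFError):
            build_pdf(field, 0.0, 5)

    def test_crossed_families_detected_as_two_components(self):
        spec = PhantomSpec(
            families=(
                {"orientation": 30.0, "period": 10.0, "waviness": 4.0},
                {"orientation": 120.0, "period": 14.0, "amplitude": 0.9,
                 "waviness": 4.0},
            ),
            mixing="domains",
            seed=1,
        )
        res = analyze_image(make_fiber_image(spec), R=2, t_fraction=0.1, B=5)
        assert res.model.k == 2
        got = sorted(res.model.b)
        # gradients sit 90 degrees from the fiber axes: (120, 30) -> (30, 120)
        assert abs(got[0] - 30.0) <= 5.0
        assert abs(got[1] - 120.0) <= 5.0

    def test_waviness_broadens_fitted_width(self):
        # photon noise smears the deterministic angle-modulation density
        # into the unimodal spread a real wavy specimen shows
        widths = []
        for w in (8.0, 20.0, 40.0):
            cs = []
            for seed in (0, 1, 2):
                spec = PhantomSpec(
                    families=({"orientation": 60.0, "waviness": w},),
                    noise_model={"kind": "poisson", "peak": 40},
                    background=0.15,
                    seed=seed,
                )
                res = analyze_image(
                    make_fiber_image(spec), R=2, t_fraction=0.1, B=5, k=1
                )
                cs.append(res.model.c[0])
            widths.append(np.mean(cs))
        assert widths[0] < widths[1] < widths[2]

    def test_rotation_equivariance_of_dominant_bin(self):
        B = 5
        for delta in (0.0, 30.0, 75.0, 140.0):
            spec = PhantomSpec(
                families=({"orientation": 20.0 + delta, "period": 10.0},),
                seed=0,
            )
            center = dominant_bin_center(make_fiber_image(spec), B=B)
            expected = (20.0 + delta + 90.0) % 180.0
            d = abs(center - expected)
            assert min(d, 180 - d) <= B


class TestNoiseImage:
    def test_poisson_counts_are_integers_and_deterministic(self):
        img = make_noise_image((64, 64), {"kind": "poisson", "mean": 2.0}, seed=5)
        again = make_noise_image((64, 64), {"kind": "poisson", "mean": 2.0}, seed=5)
        assert np.array_equal(img.pixels, img.pixels.round())
        np.testing.assert_array_equal(img.pixels, again.pixels)

    def test_gaussian_noise_is_continuous_nonnegative(self):
        img = make_noise_image(
            (64, 64), {"kind": "gaussian", "mean": 0.5, "sd": 0.1}, seed=5
        )
        assert img.pixels.min() >= 0
        assert not np.array_equal(img.pixels, img.pixels.round())

    def test_continuous_noise_has_no_exact_tie_spikes(self):
        # with continuous intensities, |gx| == |gy| has probability zero
        img = normalize_image(
            make_noise_image(
                (128, 128), {"kind": "gaussian", "mean": 1.0, "sd": 0.2}, seed=6
            )
        )
        field = compute_gradient(img, 1)
        folded = field.theta_folded[field.valid_mask]
        exact = np.isin(folded, (45.0, 90.0, 135.0, 180.0)).mean()
        assert exact < 0.001

    def test_unknown_kind_rejected(self):
        with pytest.raises(ConfigError):
            make_noise_image((8, 8), {"kind": "salt"}, seed=0)


class TestDarkCountImage:
    def test_deterministic(self):
        a = make_dark_count_image(seed=4, size=64)
        b = make_dark_count_image(seed=4, size=64)
        np.testing.assert_array_equal(a.pixels, b.pixels)

    def test_has_dark_plateaus_and_smooth_structure(self):
        img = make_dark_count_image(seed=0, size=128, dark_rate=0.0)
        # without dark counts, about half the field is exactly zero
        frac_zero = (img.pixels == 0).mean()
        assert 0.3 < frac_zero < 0.7


class TestSampledPDF:
    def test_uniform_density_flat(self):
        pdf = sample_orientation_pdf(
            a=[0.0], b=[90.0], c=[10.0], d=1.0 / 180.0, n=200_000, B=5, seed=0
        )
        assert np.max(np.abs(pdf.density - 1.0 / 180.0)) < 0.1 / 180.0

    def test_identical_seed_identical_pdf(self):
        kw = dict(a=[0.01], b=[60.0], c=[15.0], d=0.001, n=5000, B=5)
        p1 = sample_orientation_pdf(**kw, seed=8)
        p2 = sample_orientation_pdf(**kw, seed=8)
        np.testing.assert_array_equal(p1.counts, p2.counts)

    def test_fit_recovers_sampling_truth(self):
        pdf = sample_orientation_pdf(
            a=[0.012], b=[60.0], c=[15.0], d=0.001, n=100_000, B=5, seed=9
        )
        m = fit_gaussians(pdf, 1)
        assert abs(m.b[0] - 60.0) <= 2.0

    def test_invalid_weights_rejected(self):
        with pytest.raises(ConfigError):
            sample_orientation_pdf(a=[0.0], b=[90.0], c=[10.0], d=0.0,
                                   n=100, B=5, seed=0)
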