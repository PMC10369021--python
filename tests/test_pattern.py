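"""Image pattern operators, composites and the 5-D pattern distance."""

import math

import numpy as np
import pandas as pd
import pytest

from eggsig import pattern
from eggsig.pattern import (
    DISTANCE_TRAITS,
    DistanceStandardization,
    EggImage,
    adaptive_threshold,
    detect_features,
    fit_composites,
    granularity,
    pattern_distance,
    proportion_and_dispersion,
)
from eggsig.synthdata import EggImageSpec, generate_egg_image


def blank_egg(h=200, w=300, level=0.7, scale=19.0):
    yy, xx = np.mgrid[0:h, 0:w]
    mask = ((yy - (h - 1) / 2) / (h / 2)) ** 2 + ((xx - (w - 1) / 2) / (w / 2)) ** 2 <= 1.0
    return EggImage(pixels=np.where(mask, level, 0.0), mask=mask, scale=scale)


class TestAdaptiveThreshold:
    def test_constant_image_yields_no_pattern(self):
        egg = blank_egg()
        assert adaptive_threshold(egg, offset=0.05).sum() == 0

    def test_dark_disc_area_recovered(self):
        egg = blank_egg()
        yy, xx = np.mgrid[0 : egg.mask.shape[0], 0 : egg.mask.shape[1]]
        disc = (yy - 100) ** 2 + (xx - 150) ** 2 <= 20**2
        egg.pixels[disc] -= 0.4
        pat = adaptive_threshold(egg, offset=0.1)
        true_area = disc.sum()
        assert pat.sum() == pytest.approx(true_area, rel=0.15)

    def test_outside_mask_never_pattern(self):
        egg = blank_egg()
        egg.pixels[~egg.mask] = -10.0  # pathological off-egg values
        pat = adaptive_threshold(egg)
        assert not (pat & ~egg.mask).any()

    def test_window_larger_than_egg_rejected(self):
        egg = blank_egg(h=60, w=60)
        with pytest.raises(ValueError, match="extent"):
            adaptive_threshold(egg, window_mm=30.0)


class TestProportionAndDispersion:
    def test_immaculate_egg(self):
        egg = blank_egg()
        prop, disp = proportion_and_dispersion(np.zeros_like(egg.mask), egg)
        assert prop == 0.0 and math.isnan(disp)

    def test_uniform_random_pattern_dispersion_near_one(self):
        egg = blank_egg()
        rng = np.random.default_rng(3)
        pat = egg.mask & (rng.uniform(size=egg.mask.shape) < 0.2)
        prop, disp = proportion_and_dispersion(pat, egg)
        assert prop == pytest.approx(0.2, abs=0.02)
        assert disp == pytest.approx(1.0, abs=0.1)

    def test_all_markings_in_blunt_third_gives_three(self):
        egg = blank_egg()
        proj = np.broadcast_to(np.arange(egg.mask.shape[1]), egg.mask.shape)
        cut = np.quantile(proj[egg.mask], 2 / 3)
        pat = egg.mask & (proj >= cut)
        _, disp = proportion_and_dispersion(pat, egg)
        assert disp == pytest.approx(3.0, abs=0.05)


class TestGranularity:
    def test_constant_image_zero_energy(self):
        egg = blank_egg()
        spec, (tot, sd, contrast, cvar) = granularity(egg)
        assert np.allclose(spec.energies, 0.0, atol=1e-20)
        assert tot == pytest.approx(0.0, abs=1e-18)
        assert contrast == pytest.approx(0.0, abs=1e-18)

    def test_grating_peaks_in_matching_band(self):
        egg = blank_egg(h=256, w=384)
        period_px = 8.0
        xs = np.arange(egg.mask.shape[1])
        egg.pixels += 0.1 * np.sin(2 * np.pi * xs / period_px)[None, :] * egg.mask
        spec, _ = granularity(egg)
        # Fourier oracle: the peak band should contain the grating period
        peak_size_px = spec.peak_size_mm * egg.scale
        assert peak_size_px / math.sqrt(2) <= period_px < peak_size_px * math.sqrt(2)

    def test_doubling_contrast_quadruples_energy(self):
        egg = blank_egg()
        rng = np.random.default_rng(5)
        noise = rng.normal(0, 0.05, egg.pixels.shape)
        egg1 = EggImage(np.where(egg.mask, 0.7 + noise, 0), egg.mask, egg.scale)
        egg2 = EggImage(np.where(egg.mask, 0.7 + 2 * noise, 0), egg.mask, egg.scale)
        s1, _ = granularity(egg1)
        s2, _ = granularity(egg2)
        assert np.allclose(s2.energies, 4.0 * s1.energies, rtol=1e-8)

    def test_too_few_bands_rejected(self):
        with pytest.raises(ValueError, match="bands"):
            granularity(blank_egg(), n_bands=1)


class TestDetectFeatures:
    def test_blank_egg_no_features(self):
        n, size = detect_features(blank_egg())
        assert n == 0 and math.isnan(size)

    def test_twenty_sparse_spots_round_trip(self):
        spec = EggImageSpec(
            n_spots=20, spot_radius_mean=0.5, spot_radius_sd=0.0,
            non_overlapping=True, seed=4,
        )
        egg = generate_egg_image(spec)
        n, size = detect_features(egg)
        assert abs(n - 20) <= 2
        assert size == pytest.approx(math.pi * 0.25, rel=0.30)

    def test_deterministic(self):
        egg = generate_egg_image(EggImageSpec(n_spots=15, seed=8))
        assert detect_features(egg) == detect_features(egg)


class TestComposites:
    def test_perfectly_correlated_pair_explains_everything(self):
        x = np.linspace(0, 1, 30)
        df = pd.DataFrame(
            {"prop_pattern": x, "dispersion": 2 * x + 1,
             "contrast": x, "contrast_var": x + 0.5}
        )
        comp = fit_composites(df)
        assert comp.pattern_coverage.explained == pytest.approx(1.0)

    def test_uncorrelated_pair_equal_loadings(self):
        rng = np.random.default_rng(0)
        a = np.repeat([0.0, 1.0], 50)
        b = np.tile([0.0, 1.0], 50)  # exactly orthogonal to a
        df = pd.DataFrame(
            {"prop_pattern": a, "dispersion": b, "contrast": a, "contrast_var": b}
        )
        comp = fit_composites(df)
        assert np.allclose(np.abs(comp.pattern_coverage.loadings), 1 / math.sqrt(2))

    def test_scores_centred_and_signed(self):
        rng = np.random.default_rng(1)
        prop = rng.uniform(0, 1, 40)
        df = pd.DataFrame(
            {
                "prop_pattern": prop,
                "dispersion": rng.uniform(0.5, 3, 40),
                "contrast": rng.uniform(0, 1, 40),
                "contrast_var": rng.uniform(0, 1, 40),
            }
        )
        comp = fit_composites(df)
        scores = comp.score(df)
        assert abs(scores["pattern_coverage"].mean()) < 1e-10
        # sign convention: coverage increases with prop_pattern
        assert np.corrcoef(scores["pattern_coverage"], prop)[0, 1] > 0

    def test_zero_variance_rejected(self):
        df = pd.DataFrame(
            {"prop_pattern": [0.1] * 5, "dispersion": range(5),
             "contrast": range(5), "contrast_var": range(5)}
        )
        with pytest.raises(ValueError, match="variance"):
            fit_composites(df)


def _unit_std():
    return DistanceStandardization.identity()


class TestPatternDistance:
    def test_identical_eggs_zero(self):
        t = dict(zip(DISTANCE_TRAITS, [0.2, 1.5, 0.3, 0.1, 12]))
        assert pattern_distance(t, t, _unit_std()) == 0.0

    def test_unit_displacement(self):
        a = dict(zip(DISTANCE_TRAITS, [1.0, 0, 0, 0, 0]))
        b = dict(zip(DISTANCE_TRAITS, [0.0, 0, 0, 0, 0]))
        assert pattern_distance(a, b, _unit_std()) == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        a = dict(zip(DISTANCE_TRAITS, [0.3, -0.4, 1.2, 0.0, 0.5]))
        b = dict(zip(DISTANCE_TRAITS, [0.0, 0.0, 0.0, 0.0, 0.0]))
        assert pattern_distance(a, b, _unit_std()) == pytest.approx(1.393, abs=5e-4)

    def test_immaculate_dispersion_imputed(self):
        a = {"prop_pattern": 0.0, "dispersion": float("nan"),
             "total_energy": 0.0, "sd_energy": 0.0, "n_features": 0}
        b = {"prop_pattern": 0.0, "dispersion": 1.0,
             "total_energy": 0.0, "sd_energy": 0.0, "n_features": 0}
        assert pattern_distance(a, b, _unit_std()) == 0.0

    def test_metric_properties_on_random_triples(self):
        rng = np.random.default_rng(9)
        std = _unit_std()
        for _ in range(50):
            pts = [dict(zip(DISTANCE_TRAITS, rng.normal(size=5))) for _ in range(3)]
            dab = pattern_distance(pts[0], pts[1], std)
            dba = pattern_distance(pts[1], pts[0], std)
            dbc = pattern_distance(pts[1], pts[2], std)
            dac = pattern_distance(pts[0], pts[2], std)
            assert dab == pytest.approx(dba, rel=1e-12)
            assert dac <= dab + dbc + 1e-12


class TestRoundTripMonotonicity:
    def test_coverage_increases_with_spot_count(self):
        props = []
        for n_spots in (5, 60):
            egg = generate_egg_image(EggImageSpec(n_spots=n_spots, seed=2))
            pat = adaptive_threshold(egg, offset=0.1)
            props.append(pat.sum() / egg.mask.sum())
        assert props[1] > props[0]

    def test_dispersion_increases_with_pole_bias(self):
        disps = []
        for bias in (0.0, 1.0):
            egg = generate_egg_image(
                EggImageSpec(n_spots=60, pole_bias=bias, seed=6)
            )
            pat = adaptive_threshold(egg, offset=0.1)
            disps.append(proportion_and_dispersion(pat, egg)[1])
        assert disps[1] > disps[0]
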