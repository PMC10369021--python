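"""Synthetic populations, spectra, egg images and rejection experiments.

The generators emulate the statistical structure of a brood parasite-host
egg-mimicry system with individual egg "signatures":

- two species (host and parasite) drawn from overlapping polymorphic
  phenotype distributions with four soft morphs (immaculate, speckled,
  blotched, erythristic);
- strong female signatures: every female keeps one morph and one female
  effect for life, so between-female variance greatly exceeds within-female
  variance (repeatability ICC > 0.69 for every trait under the defaults);
- ground-colour reflectance spectra per female, with an optional UV
  shoulder and elevated long-wavelength reflectance for erythristic morphs;
- rejection experiments whose outcomes are Bernoulli draws from a logistic
  function of the multidimensional pattern distance between host and
  experimental egg.

Traits are generated on a latent Gaussian scale (morph mean + female effect
+ egg effect) and then transformed to their natural domain: proportions via
the logistic, positive quantities via exp, counts by rounding with a floor
at zero.  All generators are pure functions of their configuration and
seed; child random streams are spawned from the root seed in a fixed,
documented order (morph, female, egg, colour, experiment).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from eggsig import vision
from eggsig.pattern import DISTANCE_TRAITS, DistanceStandardization, EggImage

__all__ = [
    "TRAIT_NAMES",
    "SpectrumParams",
    "PopulationConfig",
    "EggImageSpec",
    "generate_population",
    "generate_spectrum",
    "generate_egg_image",
    "generate_experiments",
]

#: Latent trait order used by morph_trait_means and the sd vectors.
TRAIT_NAMES = (
    "prop_pattern",
    "dispersion",
    "total_energy",
    "sd_energy",
    "contrast",
    "contrast_var",
    "n_features",
    "mean_feature_size_mm2",
    "length_mm",
    "width_mm",
)

#: Transform from the latent Gaussian scale to each trait's natural domain.
_TRANSFORMS = {
    "prop_pattern": "logistic",
    "dispersion": "exp",
    "total_energy": "exp",
    "sd_energy": "exp",
    "contrast": "exp",
    "contrast_var": "exp",
    "n_features": "count",
    "mean_feature_size_mm2": "exp",
    "length_mm": "identity",
    "width_mm": "identity",
}

MORPHS = ("immaculate", "speckled", "blotched", "erythristic")

# Latent-scale morph means, one row per morph in MORPHS order.  Proportions
# are on the logit scale, positive traits on the log scale, counts and
# millimetre measures on their natural scale.
_DEFAULT_MORPH_MEANS = np.array(
    [
        # prop   disp   totE   sdE    contr  cvar   nfeat  mfs    len   wid
        [-7.0, 0.00, -4.0, -5.0, -5.0, -4.0, -20.0, 0.00, 25.0, 18.5],
        [-2.2, 0.18, -1.5, -2.2, -2.0, -1.8, 45.0, -1.20, 25.0, 18.5],
        [-0.8, 0.30, -0.5, -1.2, -1.0, -1.0, 25.0, 0.40, 25.0, 18.5],
        [-1.8, 0.10, -1.8, -2.5, -2.2, -2.0, 15.0, -0.20, 25.0, 18.5],
    ]
)

_DEFAULT_BETWEEN_SD = np.array([1.0, 0.25, 0.5, 0.5, 0.5, 0.5, 8.0, 0.4, 1.2, 0.9])
_DEFAULT_WITHIN_SD = np.array([0.3, 0.08, 0.15, 0.15, 0.15, 0.15, 2.5, 0.12, 0.35, 0.25])


@dataclass(frozen=True)
class SpectrumParams:
    """Smooth ground-colour reflectance parameterization on 300-700 nm.

    ``base`` and ``amp`` set a sigmoidal pale ground rising toward long
    wavelengths; ``red_amp`` adds the long-wavelength shoulder of
    erythristic (reddish-brown) eggs; ``uv_shoulder`` adds reflectance on
    the 300-315 nm band only.
    """

    base: float = 0.2
    amp: float = 0.4
    mid_nm: float = 500.0
    width_nm: float = 90.0
    red_amp: float = 0.0
    uv_shoulder: float = 0.0

    def jitter(self, rng: np.random.Generator, sd_base: float = 0.02, sd_amp: float = 0.03) -> "SpectrumParams":
        return replace(
            self,
            base=max(self.base + rng.normal(0.0, sd_base), 0.01),
            amp=max(self.amp + rng.normal(0.0, sd_amp), 0.0),
            red_amp=max(self.red_amp + rng.normal(0.0, 0.02), 0.0),
        )


_DEFAULT_COLOUR_PARAMS = {
    "immaculate": SpectrumParams(base=0.25, amp=0.45, mid_nm=480.0, red_amp=0.0),
    "speckled": SpectrumParams(base=0.20, amp=0.40, mid_nm=500.0, red_amp=0.05),
    "blotched": SpectrumParams(base=0.18, amp=0.38, mid_nm=510.0, red_amp=0.08),
    "erythristic": SpectrumParams(base=0.15, amp=0.30, mid_nm=520.0, red_amp=0.25),
}


def _as_trait_vector(x, default: np.ndarray) -> np.ndarray:
    if x is None:
        return default.copy()
    arr = np.asarray(x, dtype=float)
    if arr.ndim == 0:
        return np.full(len(TRAIT_NAMES), float(arr))
    if arr.shape != (len(TRAIT_NAMES),):
        raise ValueError(f"per-trait vector must have length {len(TRAIT_NAMES)}")
    return arr


@dataclass
class PopulationConfig:
    """Configuration of the synthetic two-species egg population."""

    n_females_host: int = 60
    n_females_parasite: int = 25
    eggs_per_female: int = 3
    morph_weights: tuple[float, float, float, float] = (0.30, 0.30, 0.25, 0.15)
    between_female_sd: np.ndarray | float | None = None
    within_female_sd: np.ndarray | float | None = None
    morph_trait_means: np.ndarray | None = None
    colour_params: dict[str, SpectrumParams] = field(
        default_factory=lambda: dict(_DEFAULT_COLOUR_PARAMS)
    )
    host_uv_shoulder: float = 0.06
    parasite_uv_shoulder: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        w = np.asarray(self.morph_weights, dtype=float)
        if w.shape != (4,) or abs(w.sum() - 1.0) > 1e-9 or np.any(w < 0):
            raise ValueError("morph_weights must be 4 non-negative probabilities summing to 1")
        self.between_female_sd = _as_trait_vector(self.between_female_sd, _DEFAULT_BETWEEN_SD)
        self.within_female_sd = _as_trait_vector(self.within_female_sd, _DEFAULT_WITHIN_SD)
        if np.any(self.between_female_sd < 0) or np.any(self.within_female_sd < 0):
            raise ValueError("trait SDs must be non-negative")
        if self.morph_trait_means is None:
            self.morph_trait_means = _DEFAULT_MORPH_MEANS.copy()
        self.morph_trait_means = np.asarray(self.morph_trait_means, dtype=float)
        if self.morph_trait_means.shape != (4, len(TRAIT_NAMES)):
            raise ValueError("morph_trait_means must be 4 x n_traits")
        if self.eggs_per_female < 1:
            raise ValueError("eggs_per_female must be >= 1")


def _transform(name: str, latent: np.ndarray) -> np.ndarray:
    kind = _TRANSFORMS[name]
    if kind == "logistic":
        return 1.0 / (1.0 + np.exp(-latent))
    if kind == "exp":
        return np.exp(latent)
    if kind == "count":
        return np.maximum(np.round(latent), 0.0)
    return latent


def generate_spectrum(
    params: SpectrumParams, wavelengths: np.ndarray | None = None
) -> vision.ReflectanceSpectrum:
    """Build a smooth, non-negative reflectance spectrum at 1-nm steps."""
    wl = vision.DEFAULT_GRID if wavelengths is None else np.asarray(wavelengths, dtype=float)
    sigmoid = 1.0 / (1.0 + np.exp(-(wl - params.mid_nm) / params.width_nm))
    red = params.red_amp / (1.0 + np.exp(-(wl - 560.0) / 30.0))
    uv = params.uv_shoulder * np.clip((315.0 - wl) / 15.0, 0.0, 1.0)
    refl = params.base + params.amp * sigmoid + red + uv
    if np.any(refl < 0):
        raise ValueError("spectrum parameters produce negative reflectance")
    return vision.ReflectanceSpectrum(wavelengths=wl, reflectance=np.clip(refl, 0.0, 1.0))


def _species_rows(
    species: str,
    n_females: int,
    uv_shoulder: float,
    cfg: PopulationConfig,
    rng_morph: np.random.Generator,
    rng_female: np.random.Generator,
    rng_egg: np.random.Generator,
    rng_colour: np.random.Generator,
    receptors: vision.ReceptorSet,
    illuminant: vision.Illuminant,
) -> list[dict]:
    k = len(TRAIT_NAMES)
    rows: list[dict] = []
    morph_idx = rng_morph.choice(4, size=n_females, p=np.asarray(cfg.morph_weights))
    for f in range(n_females):
        morph = MORPHS[morph_idx[f]]
        female_id = f"{species}_F{f:04d}"
        fem_effect = rng_female.normal(0.0, cfg.between_female_sd, size=k)
        base_params = replace(cfg.colour_params[morph], uv_shoulder=uv_shoulder)
        fem_params = base_params.jitter(rng_colour)
        spec = generate_spectrum(fem_params)
        catches = vision.cone_catch(spec, receptors, illuminant, normalize=True)
        for e in range(cfg.eggs_per_female):
            egg_effect = rng_egg.normal(0.0, cfg.within_female_sd, size=k)
            latent = cfg.morph_trait_means[morph_idx[f]] + fem_effect + egg_effect
            vals = {
                name: float(_transform(name, np.array(latent[i]))[()])
                for i, name in enumerate(TRAIT_NAMES)
            }
            if vals["n_features"] == 0:
                vals["mean_feature_size_mm2"] = float("nan")
            rows.append(
                {
                    "species": species,
                    "female_id": female_id,
                    "clutch_id": f"{female_id}_C0",
                    "egg_id": f"{female_id}_E{e}",
                    "morph": morph,
                    "length_mm": vals["length_mm"],
                    "width_mm": vals["width_mm"],
                    "shape_ratio": vals["width_mm"] / vals["length_mm"],
                    "prop_pattern": vals["prop_pattern"],
                    "dispersion": vals["dispersion"],
                    "total_energy": vals["total_energy"],
                    "sd_energy": vals["sd_energy"],
                    "contrast": vals["contrast"],
                    "contrast_var": vals["contrast_var"],
                    "n_features": vals["n_features"],
                    "mean_feature_size_mm2": vals["mean_feature_size_mm2"],
                    "catch_uv": catches.uv,
                    "catch_sw": catches.sw,
                    "catch_mw": catches.mw,
                    "catch_lw": catches.lw,
                    "catch_dbl": catches.dbl,
                }
            )
    return rows


def generate_population(config: PopulationConfig) -> pd.DataFrame:
    """Generate the phenotype table for both species.

    One row per egg; each trait is morph mean + female effect + egg effect
    on the latent scale, transformed to its natural domain.  All eggs of a
    female share her morph, female effect and ground colour.  Deterministic
    given the config seed.
    """
    if config.n_females_host < 1 and config.n_females_parasite < 1:
        raise ValueError("population has zero females")
    ss = np.random.SeedSequence(config.seed)
    streams = [np.random.default_rng(s) for s in ss.spawn(4)]
    rng_morph, rng_female, rng_egg, rng_colour = streams
    receptors = vision.violet_sensitive_tetrachromat()
    illuminant = vision.daylight_d65()
    rows = _species_rows(
        "host", config.n_females_host, config.host_uv_shoulder, config,
        rng_morph, rng_female, rng_egg, rng_colour, receptors, illuminant,
    )
    rows += _species_rows(
        "parasite", config.n_females_parasite, config.parasite_uv_shoulder, config,
        rng_morph, rng_female, rng_egg, rng_colour, receptors, illuminant,
    )
    return pd.DataFrame(rows)


@dataclass
class EggImageSpec:
    """Geometry of a synthetic egg photograph."""

    width_px: int = 500
    height_px: int = 380
    scale: float = 19.0  # px per mm, the calibration standard
    ground_level: float = 0.75
    n_spots: int = 25
    spot_radius_mean: float = 0.5  # mm
    spot_radius_sd: float = 0.1  # mm
    spot_darkness: float = 0.4
    pole_bias: float = 0.0
    non_overlapping: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.ground_level <= 1.0 and 0.0 <= self.spot_darkness <= 1.0):
            raise ValueError("ground_level and spot_darkness must lie in [0, 1]")
        if self.spot_radius_mean <= 0 or self.spot_radius_sd < 0:
            raise ValueError("spot radii must be positive")
        if not (0.0 <= self.pole_bias <= 1.0):
            raise ValueError("pole_bias must lie in [0, 1]")


def generate_egg_image(spec: EggImageSpec) -> EggImage:
    """Render a synthetic egg: pale elliptical ground with dark spots.

    The egg mask is the ellipse inscribed in the frame; the blunt pole is
    the +x (right) end.  Spots are darker discs; ``pole_bias`` tilts the
    placement density linearly toward the blunt pole (0 = uniform).  Pixels
    outside the mask are zeroed and flagged invalid by the mask.
    """
    h, w = spec.height_px, spec.width_px
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    ry, rx = h / 2.0, w / 2.0
    yy, xx = np.mgrid[0:h, 0:w]
    mask = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
    minor_axis_mm = min(h, w) / spec.scale
    if 2.0 * spec.spot_radius_mean > minor_axis_mm:
        raise ValueError("spot radius exceeds the egg minor axis")
    img = np.where(mask, spec.ground_level, 0.0).astype(float)
    rng = np.random.default_rng(spec.seed)
    spot_value = max(spec.ground_level - spec.spot_darkness, 0.0)
    placed: list[tuple[float, float, float]] = []
    attempts = 0
    while len(placed) < spec.n_spots and attempts < 200 * max(spec.n_spots, 1):
        attempts += 1
        y = rng.uniform(0, h - 1)
        x = rng.uniform(0, w - 1)
        if not mask[int(round(y)), int(round(x))]:
            continue
        if spec.pole_bias > 0:
            t = x / (w - 1)  # 0 at sharp pole, 1 at blunt pole
            accept_p = (1.0 - spec.pole_bias) + spec.pole_bias * 2.0 * t
            if rng.uniform(0, 2) > accept_p:
                continue
        r_mm = max(rng.normal(spec.spot_radius_mean, spec.spot_radius_sd), 0.05)
        r_px = r_mm * spec.scale
        if spec.non_overlapping and any(
            math.hypot(y - py, x - px) < r_px + pr + 2 for py, px, pr in placed
        ):
            continue
        placed.append((y, x, r_px))
    for y, x, r_px in placed:
        disc = (yy - y) ** 2 + (xx - x) ** 2 <= r_px**2
        img[disc & mask] = spot_value
    return EggImage(pixels=img, mask=mask, scale=spec.scale, pole_angle_deg=0.0)


def generate_experiments(
    table: pd.DataFrame,
    true_coefficients: tuple[float, float] = (-2.0, 2.5),
    n_experiments: int = 114,
    seed: int = 0,
    pairing: str = "biased",
    bias_candidates: int = 8,
    std: DistanceStandardization | None = None,
) -> pd.DataFrame:
    """Simulate host egg-rejection experiments on the synthetic population.

    Each experiment pairs a host clutch with a conspecific egg laid by a
    different female (the "experimental egg").  The rejection outcome is a
    Bernoulli draw with p = logistic(b0 + b1 * D), D the multidimensional
    pattern distance.  ``pairing='biased'`` mimics giving hosts difficult
    decisions: from ``bias_candidates`` random candidate eggs, the one with
    the smallest distance to the host egg is used; ``pairing='random'``
    picks a candidate uniformly.
    """
    hosts = table[table["species"] == "host"]
    females = hosts["female_id"].unique()
    if len(females) < 2:
        raise ValueError("experiments need at least 2 host females")
    if pairing not in ("biased", "random"):
        raise ValueError(f"unknown pairing mode {pairing!r}")
    b0, b1 = true_coefficients
    if std is None:
        std = DistanceStandardization.fit(hosts, population="host")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(5)[4])
    traits = list(DISTANCE_TRAITS)
    z = np.vstack([std.transform(_impute_row(r)) for _, r in hosts.iterrows()])
    hosts = hosts.reset_index(drop=True)
    rows = []
    for i in range(n_experiments):
        host_f = females[rng.integers(len(females))]
        host_rows = np.flatnonzero(hosts["female_id"].to_numpy() == host_f)
        host_i = int(rng.choice(host_rows))
        other = np.flatnonzero(hosts["female_id"].to_numpy() != host_f)
        m = bias_candidates if pairing == "biased" else 1
        cand = rng.choice(other, size=min(m, other.size), replace=False)
        dists = np.linalg.norm(z[cand] - z[host_i], axis=1)
        j = int(cand[np.argmin(dists)])
        d = float(np.min(dists))
        p = 1.0 / (1.0 + math.exp(-(b0 + b1 * d)))
        rows.append(
            {
                "experiment_id": f"EXP{i:04d}",
                "host_clutch_id": hosts.loc[host_i, "clutch_id"],
                "host_egg_id": hosts.loc[host_i, "egg_id"],
                "experimental_egg_id": hosts.loc[j, "egg_id"],
                "distance": d,
                "outcome": int(rng.uniform() < p),
            }
        )
    return pd.DataFrame(rows)


def _impute_row(row: pd.Series) -> pd.Series:
    s = row[list(DISTANCE_TRAITS)].astype(float)
    if s["prop_pattern"] <= 0 and pd.isna(s["dispersion"]):
        s["dispersion"] = 1.0
    return s
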