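"""Eggshell pattern quantification from calibrated grayscale images.

Three image operators quantify maculation, mirroring the standard toolkit
for egg-pattern analysis:

- adaptive thresholding splits the egg surface into "pattern" (markings)
  and "background", giving the proportion of the egg covered and how
  concentrated markings are toward the blunt pole;
- granularity analysis decomposes the image into octave-spaced spatial
  scales (Fourier bandpass) and summarizes marking contrast per scale;
- multi-scale blob detection counts distinct markings ("features") and
  measures their mean size.

At the population level two principal-component composites are formed
(pattern coverage; PC energy), and pairs of eggs are compared by the
multidimensional pattern distance: the Euclidean distance in the 5-D space
of (proportion pattern, dispersion, total energy, SD energy, number of
features), z-scored against a reference population so that no trait
dominates through its units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter
from skimage.feature import blob_log

__all__ = [
    "EggImage",
    "PatternTraits",
    "GranularitySpectrum",
    "CompositeTraits",
    "DistanceStandardization",
    "DISTANCE_TRAITS",
    "adaptive_threshold",
    "proportion_and_dispersion",
    "granularity",
    "detect_features",
    "measure_pattern",
    "fit_composites",
    "pattern_distance",
]

#: Trait columns entering the multidimensional pattern distance.  Mean
#: feature size is deliberately excluded: it is undefined for immaculate
#: eggs, which must remain comparable.
DISTANCE_TRAITS = ("prop_pattern", "dispersion", "total_energy", "sd_energy", "n_features")


@dataclass
class EggImage:
    """Calibrated grayscale egg photograph.

    ``pixels`` are reflectance-like values in [0, 1]; ``mask`` flags pixels
    on the egg; ``scale`` is px per mm (19 px/mm is the calibration standard
    used throughout); ``pole_angle_deg`` is the direction of the egg's major
    axis pointing toward the blunt pole, measured from the +x (column) axis,
    y down (image convention).
    """

    pixels: np.ndarray
    mask: np.ndarray
    scale: float = 19.0
    pole_angle_deg: float = 0.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.pixels.ndim != 2 or self.mask.shape != self.pixels.shape:
            raise ValueError("pixels must be 2-D and mask the same shape")
        if not self.mask.any():
            raise ValueError("egg mask is empty")
        if self.scale <= 0:
            raise ValueError("scale (px/mm) must be positive")
        if not np.all(np.isfinite(self.pixels[self.mask])):
            raise ValueError("pixels must be finite inside the mask")


@dataclass
class PatternTraits:
    """Per-egg pattern variables; NaN marks metrics undefined for the egg."""

    prop_pattern: float
    dispersion: float
    total_energy: float
    sd_energy: float
    contrast: float
    contrast_var: float
    n_features: int
    mean_feature_size: float  # mm^2; NaN when n_features == 0

    def as_dict(self) -> dict[str, float]:
        return {
            "prop_pattern": self.prop_pattern,
            "dispersion": self.dispersion,
            "total_energy": self.total_energy,
            "sd_energy": self.sd_energy,
            "contrast": self.contrast,
            "contrast_var": self.contrast_var,
            "n_features": self.n_features,
            "mean_feature_size_mm2": self.mean_feature_size,
        }


@dataclass
class GranularitySpectrum:
    sizes_mm: np.ndarray
    energies: np.ndarray

    @property
    def total_energy(self) -> float:
        return float(self.energies.sum())

    @property
    def sd_energy(self) -> float:
        return float(self.energies.std(ddof=0))

    @property
    def contrast(self) -> float:
        return float(self.energies.max())

    @property
    def peak_size_mm(self) -> float:
        return float(self.sizes_mm[int(np.argmax(self.energies))])


def _masked_local_mean(pixels: np.ndarray, mask: np.ndarray, window_px: int) -> np.ndarray:
    filled = np.where(mask, pixels, 0.0)
    num = uniform_filter(filled, size=window_px, mode="constant")
    den = uniform_filter(mask.astype(float), size=window_px, mode="constant")
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / den, 0.0)


def adaptive_threshold(egg: EggImage, window_mm: float = 3.0, offset: float = 0.05) -> np.ndarray:
    """Binary pattern mask: pixel is pattern iff darker than its local mean.

    The local mean is computed over a ``window_mm`` square neighbourhood
    using only on-egg pixels, so off-egg background never leaks into the
    threshold.  Only dark-on-light maculation is detected (value < local
    mean - ``offset``), appropriate for dark markings on a pale ground.
    """
    window_px = int(round(window_mm * egg.scale))
    window_px += 1 - window_px % 2  # odd window
    if window_px < 3:
        raise ValueError("threshold window is below 3 px at this scale")
    rows = np.any(egg.mask, axis=1).sum()
    cols = np.any(egg.mask, axis=0).sum()
    if window_px > max(rows, cols):
        raise ValueError("threshold window exceeds the egg extent")
    local_mean = _masked_local_mean(egg.pixels, egg.mask, window_px)
    return egg.mask & (egg.pixels < local_mean - offset)


def _axis_projection(egg: EggImage) -> np.ndarray:
    """Projection of mask-pixel coordinates onto the blunt-pole direction."""
    theta = math.radians(egg.pole_angle_deg)
    ys, xs = np.nonzero(egg.mask)
    return xs * math.cos(theta) + ys * math.sin(theta)


def proportion_and_dispersion(pattern_mask: np.ndarray, egg: EggImage) -> tuple[float, float]:
    """Coverage and pole concentration of the thresholded pattern.

    ``prop_pattern`` is the fraction of on-egg pixels classified as pattern.
    ``dispersion`` is coverage within the blunt-pole third of the egg
    (equal-area thirds along the major axis) divided by overall coverage:
    1 for uniformly spread markings, 3 when all markings sit in the blunt
    third, NaN for immaculate eggs.
    """
    n_egg = int(egg.mask.sum())
    if n_egg == 0:
        raise ValueError("egg mask is empty")
    pat = pattern_mask & egg.mask
    n_pat = int(pat.sum())
    prop = n_pat / n_egg
    if n_pat == 0:
        return 0.0, float("nan")
    proj = _axis_projection(egg)
    cut = np.quantile(proj, 2.0 / 3.0)
    blunt = proj >= cut
    pat_flat = pat[np.nonzero(egg.mask)]
    n_blunt_egg = int(blunt.sum())
    n_blunt_pat = int((pat_flat & blunt).sum())
    coverage_blunt = n_blunt_pat / n_blunt_egg
    return prop, coverage_blunt / prop


def _bandpass_images(
    egg: EggImage, sizes_px: np.ndarray
) -> tuple[list[np.ndarray], np.ndarray]:
    """Fourier bandpass of the mean-padded image into octave annuli."""
    inside = egg.pixels[egg.mask]
    filled = np.where(egg.mask, egg.pixels, inside.mean())
    filled = filled - filled.mean()
    spec = np.fft.fft2(filled)
    fy = np.fft.fftfreq(filled.shape[0])[:, None]
    fx = np.fft.fftfreq(filled.shape[1])[None, :]
    freq = np.hypot(fy, fx)
    bands = []
    root2 = math.sqrt(2.0)
    for s in sizes_px:
        lo, hi = 1.0 / (s * root2), root2 / s
        keep = (freq >= lo) & (freq < hi)
        bands.append(np.fft.ifft2(spec * keep).real)
    return bands, freq


def granularity(
    egg: EggImage,
    n_bands: int = 7,
    min_size_mm: float = 0.25,
    max_size_mm: float = 16.0,
) -> tuple[GranularitySpectrum, tuple[float, float, float, float]]:
    """Granularity spectrum over octave-spaced marking sizes.

    Each band isolates image structure at one spatial scale (Fourier
    annulus around the band size); its energy is the variance of the
    band-filtered pixels inside the egg mask.  Returns the spectrum and the
    four scalar summaries (total energy, SD energy, contrast = peak band
    energy, contrast variability = SD of the summed bandpassed image).
    """
    if n_bands < 2:
        raise ValueError("granularity needs at least 2 bands")
    sizes_mm = np.geomspace(min_size_mm, max_size_mm, n_bands)
    sizes_px = sizes_mm * egg.scale
    bands, _ = _bandpass_images(egg, sizes_px)
    energies = np.array([b[egg.mask].var(ddof=0) for b in bands])
    spectrum = GranularitySpectrum(sizes_mm=sizes_mm, energies=energies)
    combined = np.sum(bands, axis=0)
    contrast_var = float(combined[egg.mask].std(ddof=0))
    return spectrum, (spectrum.total_energy, spectrum.sd_energy, spectrum.contrast, contrast_var)


def detect_features(
    egg: EggImage,
    min_radius_mm: float = 0.15,
    max_radius_mm: float = 3.0,
    threshold: float = 0.05,
    num_sigma: int = 10,
) -> tuple[int, float]:
    """Count distinct markings via multi-scale blob detection.

    Dark markings are detected as Laplacian-of-Gaussian extrema of the
    inverted image within the egg mask.  Returns the feature count and the
    mean blob area in mm^2 (NaN when no features are found, since mean
    feature size is meaningless for immaculate eggs).  Deterministic: no
    randomness is involved.
    """
    inside = egg.pixels[egg.mask]
    inverted = np.where(egg.mask, inside.mean() - egg.pixels, 0.0)
    sigma_lo = max(min_radius_mm * egg.scale / math.sqrt(2.0), 1.0)
    sigma_hi = max(max_radius_mm * egg.scale / math.sqrt(2.0), sigma_lo + 1.0)
    blobs = blob_log(
        inverted,
        min_sigma=sigma_lo,
        max_sigma=sigma_hi,
        num_sigma=num_sigma,
        threshold=threshold,
    )
    if blobs.size == 0:
        return 0, float("nan")
    ys = np.clip(blobs[:, 0].astype(int), 0, egg.mask.shape[0] - 1)
    xs = np.clip(blobs[:, 1].astype(int), 0, egg.mask.shape[1] - 1)
    keep = egg.mask[ys, xs]
    blobs = blobs[keep]
    if blobs.shape[0] == 0:
        return 0, float("nan")
    radii_px = blobs[:, 2] * math.sqrt(2.0)
    areas_mm2 = math.pi * (radii_px / egg.scale) ** 2
    return int(blobs.shape[0]), float(areas_mm2.mean())


def measure_pattern(
    egg: EggImage,
    window_mm: float = 3.0,
    offset: float = 0.05,
    **granularity_kwargs,
) -> PatternTraits:
    """Run all three operators on one egg and collect its pattern traits."""
    pat = adaptive_threshold(egg, window_mm=window_mm, offset=offset)
    prop, disp = proportion_and_dispersion(pat, egg)
    _, (total_e, sd_e, contrast, contrast_var) = granularity(egg, **granularity_kwargs)
    n_feat, mean_size = detect_features(egg)
    return PatternTraits(
        prop_pattern=prop,
        dispersion=disp,
        total_energy=total_e,
        sd_energy=sd_e,
        contrast=contrast,
        contrast_var=contrast_var,
        n_features=n_feat,
        mean_feature_size=mean_size,
    )


def _pc1_2x2(r: float) -> tuple[np.ndarray, float]:
    """PC1 loadings and explained-variance share of a 2x2 correlation matrix."""
    sign = 1.0 if r >= 0 else -1.0
    loadings = np.array([1.0, sign]) / math.sqrt(2.0)
    explained = (1.0 + abs(r)) / 2.0
    return loadings, explained


@dataclass
class CompositePair:
    traits: tuple[str, str]
    means: np.ndarray
    sds: np.ndarray
    loadings: np.ndarray
    explained: float

    def score(self, table: pd.DataFrame) -> np.ndarray:
        z = (table[list(self.traits)].to_numpy(dtype=float) - self.means) / self.sds
        return z @ self.loadings


@dataclass
class CompositeTraits:
    """Population-level PC1 composites: pattern coverage and PC energy.

    Pattern coverage combines proportion pattern with pole dispersion;
    PC energy combines granularity contrast with contrast variability.
    Standardization statistics are retained so held-out eggs can be scored
    against the fitting population.
    """

    pattern_coverage: CompositePair
    pc_energy: CompositePair

    def score(self, table: pd.DataFrame) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pattern_coverage": self.pattern_coverage.score(table),
                "pc_energy": self.pc_energy.score(table),
            },
            index=table.index,
        )


def _fit_pair(table: pd.DataFrame, traits: tuple[str, str], anchor: str) -> CompositePair:
    x = table[list(traits)].to_numpy(dtype=float)
    if x.shape[0] < 3:
        raise ValueError("composite PCA needs at least 3 complete eggs")
    means = x.mean(axis=0)
    sds = x.std(axis=0, ddof=1)
    if np.any(sds <= 0):
        raise ValueError(f"zero variance in composite inputs {traits}")
    r = float(np.corrcoef(x, rowvar=False)[0, 1])
    loadings, explained = _pc1_2x2(r)
    if loadings[list(traits).index(anchor)] < 0:
        loadings = -loadings
    return CompositePair(traits=traits, means=means, sds=sds, loadings=loadings, explained=explained)


def fit_composites(table: pd.DataFrame) -> CompositeTraits:
    """Fit both composite PCs on a population table (correlation-matrix PCA).

    Sign convention: pattern coverage increases with proportion pattern and
    PC energy increases with contrast.  Rows with missing inputs (e.g.
    dispersion of immaculate eggs before imputation) are dropped per pair.
    """
    cov_tab = table.dropna(subset=["prop_pattern", "dispersion"])
    en_tab = table.dropna(subset=["contrast", "contrast_var"])
    return CompositeTraits(
        pattern_coverage=_fit_pair(cov_tab, ("prop_pattern", "dispersion"), "prop_pattern"),
        pc_energy=_fit_pair(en_tab, ("contrast", "contrast_var"), "contrast"),
    )


@dataclass
class DistanceStandardization:
    """Per-trait means/SDs scaling the 5-D pattern space.

    Fitted on the pooled population under analysis (z-score mode, default)
    so that the Euclidean distance weights every trait equally; ``raw`` mode
    leaves traits in their native units.
    """

    means: pd.Series
    sds: pd.Series
    population: str = "pooled"

    def __post_init__(self) -> None:
        if np.any(self.sds.to_numpy() <= 0):
            raise ValueError("standardization SDs must be positive")

    @classmethod
    def fit(cls, table: pd.DataFrame, population: str = "pooled") -> "DistanceStandardization":
        t = impute_immaculate(table)[list(DISTANCE_TRAITS)].astype(float)
        return cls(means=t.mean(), sds=t.std(ddof=1), population=population)

    @classmethod
    def identity(cls) -> "DistanceStandardization":
        idx = pd.Index(DISTANCE_TRAITS)
        return cls(
            means=pd.Series(0.0, index=idx), sds=pd.Series(1.0, index=idx), population="raw"
        )

    def transform(self, traits: pd.Series | dict) -> np.ndarray:
        s = pd.Series(traits)
        vals = s.reindex(list(DISTANCE_TRAITS)).astype(float)
        if vals.isna().any():
            missing = list(vals.index[vals.isna()])
            raise ValueError(f"missing distance traits {missing}; impute first")
        return ((vals - self.means[list(DISTANCE_TRAITS)]) / self.sds[list(DISTANCE_TRAITS)]).to_numpy()


def impute_immaculate(table: pd.DataFrame) -> pd.DataFrame:
    """Impute dispersion = 1 (uniform) for immaculate eggs (prop_pattern 0).

    Keeps immaculate eggs inside the 5-D pattern space: all their remaining
    distance traits are well defined.
    """
    out = table.copy()
    immaculate = out["prop_pattern"] <= 0
    out.loc[immaculate & out["dispersion"].isna(), "dispersion"] = 1.0
    return out


def pattern_distance(
    a: pd.Series | dict | PatternTraits,
    b: pd.Series | dict | PatternTraits,
    std: DistanceStandardization,
) -> float:
    """Multidimensional pattern distance between two eggs.

    Euclidean distance of the standardized 5-trait vectors; symmetric, zero
    iff the traits coincide.
    """
    def _prep(t):
        if isinstance(t, PatternTraits):
            t = t.as_dict()
        s = pd.Series(t, dtype=float)
        if s.get("prop_pattern", 1.0) <= 0 and pd.isna(s.get("dispersion")):
            s["dispersion"] = 1.0
        return s

    za, zb = std.transform(_prep(a)), std.transform(_prep(b))
    return float(np.linalg.norm(za - zb))
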