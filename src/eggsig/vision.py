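"""Avian colour vision modelling.

Converts eggshell reflectance spectra into photoreceptor quantum catches for
a violet-sensitive (VS) tetrachromat viewer and evaluates colour differences
with the receptor-noise-limited (RNL) discrimination model.  Distances are
expressed in just-noticeable differences (JNDs); a chromatic or achromatic
contrast below 1 JND means the two stimuli are predicted to be
indiscriminable to the modelled receiver.

The default receiver is a VS-type tetrachromat parameterized from a
published visual-pigment template (peak sensitivities typical of the Indian
peafowl, a standard proxy for VS passerine-like vision), with four single
cones (UV/violet-, short-, medium-, long-wavelength sensitive) driving
chromatic comparisons and a double cone driving the luminance channel.
Users may substitute their own sensitivity curves, cone-density ratios,
Weber fractions and illuminants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ReflectanceSpectrum",
    "Illuminant",
    "ReceptorSet",
    "ConeCatches",
    "SINGLE_CONE_NAMES",
    "pigment_template",
    "violet_sensitive_tetrachromat",
    "daylight_d65",
    "cone_catch",
    "chromatic_jnd",
    "achromatic_jnd",
    "receptor_noise",
    "tetrahedral_coordinates",
    "catches_from_tetrahedral",
    "colour_centroid",
]

SINGLE_CONE_NAMES = ("uv", "sw", "mw", "lw")

DEFAULT_GRID = np.arange(300.0, 701.0)


@dataclass(frozen=True)
class ReflectanceSpectrum:
    """Per-egg ground-colour reflectance over a wavelength grid (nm)."""

    wavelengths: np.ndarray
    reflectance: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        refl = np.asarray(self.reflectance, dtype=float)
        if wl.ndim != 1 or refl.shape != wl.shape:
            raise ValueError("wavelengths and reflectance must be 1-D and equal length")
        if wl.size < 2 or np.any(np.diff(wl) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if np.any(refl < 0) or not np.all(np.isfinite(refl)):
            raise ValueError("reflectance must be finite and non-negative")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "reflectance", refl)


@dataclass(frozen=True)
class Illuminant:
    """Relative quantal irradiance over a wavelength grid (nm)."""

    wavelengths: np.ndarray
    irradiance: np.ndarray
    label: str = "custom"

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        irr = np.asarray(self.irradiance, dtype=float)
        if wl.ndim != 1 or irr.shape != wl.shape:
            raise ValueError("wavelengths and irradiance must be 1-D and equal length")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if np.any(irr < 0):
            raise ValueError("irradiance must be non-negative")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "irradiance", irr)


@dataclass(frozen=True)
class ReceptorSet:
    """Receiver description: sensitivity curves plus the noise model.

    ``sensitivities`` holds one row per channel in the order
    (uv, sw, mw, lw, dbl), each normalized to unit area on ``wavelengths``.
    Receptor noise for single cone *i* is
    ``e_i = weber_fraction * sqrt(max(density) / density_i)``, anchoring the
    Weber fraction to the most abundant cone class.
    """

    wavelengths: np.ndarray
    sensitivities: np.ndarray
    relative_densities: np.ndarray = field(
        default_factory=lambda: np.array([1.0, 2.0, 2.0, 4.0])
    )
    weber_fraction: float = 0.1
    weber_fraction_achromatic: float = 0.34
    label: str = "vs-tetrachromat"

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        sens = np.asarray(self.sensitivities, dtype=float)
        dens = np.asarray(self.relative_densities, dtype=float)
        if sens.shape != (5, wl.size):
            raise ValueError("sensitivities must be a 5 x n_wavelength array")
        if np.any(sens < 0):
            raise ValueError("sensitivities must be non-negative")
        if np.any(np.trapezoid(sens, wl) <= 0):
            raise ValueError("each sensitivity curve must have positive area")
        if dens.shape != (4,) or np.any(dens <= 0):
            raise ValueError("relative_densities must be 4 positive values")
        if self.weber_fraction <= 0 or self.weber_fraction_achromatic <= 0:
            raise ValueError("Weber fractions must be positive")
        sens = sens / np.trapezoid(sens, wl)[:, None]
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "sensitivities", sens)
        object.__setattr__(self, "relative_densities", dens)


@dataclass(frozen=True)
class ConeCatches:
    """Quantum catches of the four single cones plus the double cone."""

    uv: float
    sw: float
    mw: float
    lw: float
    dbl: float

    def single(self) -> np.ndarray:
        return np.array([self.uv, self.sw, self.mw, self.lw], dtype=float)

    def relative(self) -> np.ndarray:
        """Single-cone catches as proportions summing to one."""
        q = self.single()
        total = q.sum()
        if total <= 0:
            raise ValueError("cannot normalize all-zero catches")
        return q / total


def pigment_template(wavelengths: np.ndarray, lambda_max: float) -> np.ndarray:
    """A1 visual-pigment absorbance template (alpha plus beta band).

    Standard rhodopsin template parameterized only by the peak wavelength
    ``lambda_max``; widely used to reconstruct cone sensitivities when
    measured curves are unavailable.
    """
    wl = np.asarray(wavelengths, dtype=float)
    x = lambda_max / wl
    a = 0.8795 + 0.0459 * np.exp(-((lambda_max - 300.0) ** 2) / 11940.0)
    alpha = 1.0 / (
        np.exp(69.7 * (a - x))
        + np.exp(28.0 * (0.922 - x))
        + np.exp(-14.9 * (1.104 - x))
        + 0.674
    )
    lm_beta = 189.0 + 0.315 * lambda_max
    bw = -40.5 + 0.195 * lambda_max
    beta = 0.26 * np.exp(-(((wl - lm_beta) / bw) ** 2))
    return np.clip(alpha + beta, 0.0, None)


def violet_sensitive_tetrachromat(
    wavelengths: np.ndarray | None = None,
    lambda_max: tuple[float, float, float, float, float] = (432.0, 477.0, 537.0, 605.0, 567.0),
    **noise_kwargs,
) -> ReceptorSet:
    """Built-in VS-tetrachromat receptor set from the pigment template.

    ``lambda_max`` orders the peaks as (uv/violet, sw, mw, lw, double cone).
    """
    wl = DEFAULT_GRID if wavelengths is None else np.asarray(wavelengths, dtype=float)
    sens = np.vstack([pigment_template(wl, lm) for lm in lambda_max])
    return ReceptorSet(wavelengths=wl, sensitivities=sens, **noise_kwargs)


def daylight_d65(wavelengths: np.ndarray | None = None) -> Illuminant:
    """Smooth standard-daylight approximation in relative quanta.

    Modelled as a 6504 K black-body photon spectrum, the correlated colour
    temperature of standard daylight; adequate for open, well-lit nests and
    swappable for a measured irradiance table via :class:`Illuminant`.
    """
    wl = DEFAULT_GRID if wavelengths is None else np.asarray(wavelengths, dtype=float)
    lam = wl * 1e-9
    hc_over_kT = 6.62607015e-34 * 2.99792458e8 / (1.380649e-23 * 6504.0)
    # photon radiance ~ lambda^-4 / (exp(hc/(lambda k T)) - 1)
    quanta = lam**-4 / np.expm1(hc_over_kT / lam)
    return Illuminant(wavelengths=wl, irradiance=quanta / quanta.max(), label="d65-6504K")


def _interp_to(grid: np.ndarray, wl: np.ndarray, values: np.ndarray) -> np.ndarray:
    if grid[0] < wl[0] - 1e-9 or grid[-1] > wl[-1] + 1e-9:
        raise ValueError(
            f"grid [{grid[0]}, {grid[-1]}] nm extends beyond data range [{wl[0]}, {wl[-1]}] nm"
        )
    return np.interp(grid, wl, values)


def cone_catch(
    spectrum: ReflectanceSpectrum,
    receptors: ReceptorSet,
    illuminant: Illuminant,
    normalize: bool = True,
) -> ConeCatches:
    """Quantum catch per channel: trapezoidal integral of R * I * S.

    With ``normalize`` the catches are von-Kries scaled, i.e. divided by the
    catch of a perfect white (R = 1) under the same illuminant, so a perfect
    white scores 1.0 in every channel.
    """
    wl = receptors.wavelengths
    refl = _interp_to(wl, spectrum.wavelengths, spectrum.reflectance)
    irr = _interp_to(wl, illuminant.wavelengths, illuminant.irradiance)
    raw = np.trapezoid(refl * irr * receptors.sensitivities, wl)
    if normalize:
        white = np.trapezoid(irr * receptors.sensitivities, wl)
        if np.any(white <= 0):
            raise ValueError("illuminant gives zero white-point catch in a channel")
        raw = raw / white
    return ConeCatches(*raw)


def receptor_noise(receptors: ReceptorSet) -> np.ndarray:
    """Noise e_i per single cone from the Weber fraction and density ratios."""
    dens = receptors.relative_densities
    return receptors.weber_fraction * np.sqrt(dens.max() / dens)


def _log_signals(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("JND requires strictly positive cone catches (log signal)")
    return np.log(a / b)


def chromatic_jnd(
    a: ConeCatches, b: ConeCatches, receptors: ReceptorSet, noise: np.ndarray | None = None
) -> float:
    """Receptor-noise-limited chromatic distance in JNDs.

    Uses the log-linear signal form df_i = ln(a_i / b_i) over the single
    cones and the general n-channel RNL quadratic

        dS^2 = sum_{i<j} (prod_{k != i,j} e_k)^2 (df_i - df_j)^2
               / sum_i (prod_{k != i} e_k)^2

    which reduces to the familiar closed forms for di-, tri- and
    tetrachromats.  ``noise`` overrides the per-cone noise vector (its
    length sets the number of channels compared).
    """
    e = receptor_noise(receptors) if noise is None else np.asarray(noise, dtype=float)
    n = e.size
    df = _log_signals(a.single()[:n], b.single()[:n])
    num = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            others = [k for k in range(n) if k not in (i, j)]
            num += np.prod(e[others]) ** 2 * (df[i] - df[j]) ** 2
    den = sum(np.prod(np.delete(e, i)) ** 2 for i in range(n))
    return float(np.sqrt(num / den))


def achromatic_jnd(a: ConeCatches, b: ConeCatches, receptors: ReceptorSet) -> float:
    """Luminance contrast in JNDs: |ln(a_dbl / b_dbl)| / achromatic Weber."""
    df = _log_signals(np.array([a.dbl]), np.array([b.dbl]))[0]
    return float(abs(df) / receptors.weber_fraction_achromatic)


# Regular tetrahedron vertices for (uv, sw, mw, lw); the achromatic point
# (equal relative catches) sits at the origin.
_TETRA_VERTICES = np.array(
    [
        [1.0, 1.0, 1.0],
        [1.0, -1.0, -1.0],
        [-1.0, 1.0, -1.0],
        [-1.0, -1.0, 1.0],
    ]
)


def tetrahedral_coordinates(catches: ConeCatches) -> np.ndarray:
    """Map relative single-cone catches to Cartesian tetrahedral coordinates."""
    return tetrahedral_from_relative(catches.relative())


def tetrahedral_from_relative(q: np.ndarray) -> np.ndarray:
    return np.asarray(q, dtype=float) @ _TETRA_VERTICES


def catches_from_tetrahedral(xyz: np.ndarray, dbl: float = 1.0) -> ConeCatches:
    """Invert the tetrahedral map back to relative catches (barycentric)."""
    aug = np.vstack([_TETRA_VERTICES.T, np.ones(4)])
    rhs = np.append(np.asarray(xyz, dtype=float), 1.0)
    q = np.linalg.lstsq(aug, rhs, rcond=None)[0]
    return ConeCatches(*q, dbl=dbl)


def colour_centroid(catches: list[ConeCatches]) -> ConeCatches:
    """Population centroid in tetrahedral colour space.

    The mean of Cartesian tetrahedral coordinates, mapped back to relative
    catches; the luminance channel is averaged arithmetically.
    """
    if not catches:
        raise ValueError("cannot take the centroid of an empty population")
    xyz = np.mean([tetrahedral_coordinates(c) for c in catches], axis=0)
    dbl = float(np.mean([c.dbl for c in catches]))
    return catches_from_tetrahedral(xyz, dbl=dbl)
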