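"""Spectral forward model of jaundiced-skin imaging.

A small exploratory model of how skin chromophores, a yellowish-green
band-pass filter and a three-diode camera combine into RGB intensities:
bilirubin absorbs broadly in the blue with a maximum near 460 nm, oxygenated
haemoglobin shows its double peak near 540/576 nm, melanin absorption falls
monotonically with wavelength. Reflectance follows a two-pass Beer-Lambert
law; channel values integrate reflected light against Gaussian camera bands.

This module deliberately contrasts with the phenomenological cohort renderer:
under absorption physics the blue channel *decreases* with bilirubin, whereas
the measured study statistics (which the cohort model is calibrated to) show
a positive blue-intensity correlation. Both behaviours are real properties of
their respective models and are tested separately; no quantitative clinical
prediction is attempted here.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "SpectralCurve",
    "SkinComposition",
    "default_grid",
    "bilirubin_extinction",
    "haemoglobin_extinction",
    "melanin_extinction",
    "wratten11_transmission",
    "camera_sensitivities",
    "flat_illuminant",
    "diffuse_reflectance",
    "render_rgb",
]

VISIBLE_RANGE = (380.0, 780.0)

#: Wratten No. 11 half-maximum (cut-on/cut-off) and peak wavelengths, nm
WRATTEN11_CUT_ON = 483.0
WRATTEN11_PEAK = 516.0
WRATTEN11_CUT_OFF = 589.0

BILIRUBIN_PEAK_NM = 460.0


class SpectralError(ValueError):
    pass


@dataclass(frozen=True)
class SpectralCurve:
    """Nonnegative per-wavelength magnitudes on a strictly increasing nm grid."""

    wavelengths: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=np.float64)
        v = np.asarray(self.values, dtype=np.float64)
        if wl.shape != v.shape or wl.ndim != 1:
            raise SpectralError("wavelengths and values must be equal-length 1-D")
        if not np.all(np.diff(wl) > 0):
            raise SpectralError("wavelength grid must be strictly increasing")
        if wl[0] < VISIBLE_RANGE[0] or wl[-1] > VISIBLE_RANGE[1]:
            raise SpectralError(
                f"grid outside the visible range {VISIBLE_RANGE} nm"
            )
        if np.any(v < 0):
            raise SpectralError("spectral values must be nonnegative")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "values", v)

    def to_csv(self, path: str | Path) -> None:
        np.savetxt(
            Path(path),
            np.column_stack([self.wavelengths, self.values]),
            delimiter=",",
            header="wavelength_nm,value",
            comments="",
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "SpectralCurve":
        arr = np.loadtxt(Path(path), delimiter=",", skiprows=1)
        return cls(arr[:, 0], arr[:, 1])


@dataclass(frozen=True)
class SkinComposition:
    """Relative chromophore concentrations and effective optical path."""

    bilirubin_conc: float = 0.0
    haemoglobin_conc: float = 0.0
    melanin_conc: float = 0.0
    effective_path: float = 1.0

    def __post_init__(self) -> None:
        for name in ("bilirubin_conc", "haemoglobin_conc", "melanin_conc"):
            if getattr(self, name) < 0:
                raise SpectralError(f"{name} must be nonnegative")
        if self.effective_path <= 0:
            raise SpectralError("effective_path must be positive")


def default_grid() -> np.ndarray:
    """380-780 nm at 1 nm steps."""
    return np.arange(VISIBLE_RANGE[0], VISIBLE_RANGE[1] + 1.0, 1.0)


def _gauss(wl: np.ndarray, centre: float, fwhm: float) -> np.ndarray:
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    return np.exp(-0.5 * ((wl - centre) / sigma) ** 2)


def bilirubin_extinction(grid: np.ndarray, fwhm: float = 100.0) -> SpectralCurve:
    """Bilirubin's broad blue absorption band, peak-normalised at 460 nm."""
    wl = np.asarray(grid, dtype=np.float64)
    return SpectralCurve(wl, _gauss(wl, BILIRUBIN_PEAK_NM, fwhm))


def haemoglobin_extinction(grid: np.ndarray) -> SpectralCurve:
    """Parametric oxyhaemoglobin stand-in: double peak near 540/576 nm."""
    wl = np.asarray(grid, dtype=np.float64)
    v = _gauss(wl, 540.0, 35.0) + 0.85 * _gauss(wl, 576.0, 30.0)
    return SpectralCurve(wl, v / v.max())


def melanin_extinction(grid: np.ndarray) -> SpectralCurve:
    """Parametric melanin stand-in: monotone decreasing with wavelength."""
    wl = np.asarray(grid, dtype=np.float64)
    v = (VISIBLE_RANGE[0] / wl) ** 3.0
    return SpectralCurve(wl, v)


def wratten11_transmission(grid: np.ndarray) -> SpectralCurve:
    """Wratten No. 11 band-pass: T = 0.5 at 483/589 nm, T = 1 at 516 nm.

    Cut-on and cut-off are taken as the half-maximum points (the standard
    filter-datasheet convention). The curve is a piecewise super-Gaussian of
    order 4, which hits the half-maxima exactly, stays smooth and unimodal,
    and rejects out-of-band light (T < 1e-3 outside roughly [430, 650] nm).
    """
    wl = np.asarray(grid, dtype=np.float64)
    left_hw = WRATTEN11_PEAK - WRATTEN11_CUT_ON  # 33 nm
    right_hw = WRATTEN11_CUT_OFF - WRATTEN11_PEAK  # 73 nm
    hw = np.where(wl <= WRATTEN11_PEAK, left_hw, right_hw)
    t = np.exp(-np.log(2.0) * ((wl - WRATTEN11_PEAK) / hw) ** 4)
    return SpectralCurve(wl, t)


def camera_sensitivities(
    grid: np.ndarray,
    centres: tuple[float, float, float] = (600.0, 530.0, 460.0),
    fwhm: float = 70.0,
) -> tuple[SpectralCurve, SpectralCurve, SpectralCurve]:
    """Gaussian R/G/B photodiode bands (sensor curves are device-specific
    and unpublished; these are generic consumer-camera shapes)."""
    wl = np.asarray(grid, dtype=np.float64)
    return tuple(SpectralCurve(wl, _gauss(wl, c, fwhm)) for c in centres)


def flat_illuminant(grid: np.ndarray) -> SpectralCurve:
    """Equal-energy illuminant (the dermatoscope LED spectrum is unknown)."""
    wl = np.asarray(grid, dtype=np.float64)
    return SpectralCurve(wl, np.ones_like(wl))


def diffuse_reflectance(
    composition: SkinComposition,
    chromophore_curves: dict[str, SpectralCurve] | None = None,
    grid: np.ndarray | None = None,
) -> SpectralCurve:
    """Two-pass Beer-Lambert reflectance of the skin stack.

    R(λ) = exp(-2 · path · Σ_i conc_i · ε_i(λ)), values in (0, 1]. The factor
    2 accounts for light traversing the absorbing layer twice (in and out).
    """
    if chromophore_curves is None:
        wl = default_grid() if grid is None else np.asarray(grid, dtype=np.float64)
        chromophore_curves = {
            "bilirubin": bilirubin_extinction(wl),
            "haemoglobin": haemoglobin_extinction(wl),
            "melanin": melanin_extinction(wl),
        }
    curves = chromophore_curves
    wl = next(iter(curves.values())).wavelengths
    conc = {
        "bilirubin": composition.bilirubin_conc,
        "haemoglobin": composition.haemoglobin_conc,
        "melanin": composition.melanin_conc,
    }
    absorbance = np.zeros_like(wl)
    for name, curve in curves.items():
        if not np.array_equal(curve.wavelengths, wl):
            raise SpectralError("chromophore curves on mismatched grids")
        absorbance += conc.get(name, 0.0) * curve.values
    r = np.exp(-2.0 * composition.effective_path * absorbance)
    return SpectralCurve(wl, r)


def _round_half_away(x: float) -> int:
    return int(np.sign(x) * np.floor(abs(x) + 0.5))


def render_rgb(
    reflectance: SpectralCurve,
    illuminant: SpectralCurve,
    camera: tuple[SpectralCurve, SpectralCurve, SpectralCurve],
    filter_curve: SpectralCurve | None = None,
) -> tuple[int, int, int]:
    """Integrate reflected light into 8-bit channel values.

    channel_c = round(255 · ∫ R·I·S_c·T dλ / ∫ I·S_c dλ), clipped to [0, 255];
    a perfect reflector with no filter maps to (255, 255, 255). Trapezoidal
    integration on the common grid; mismatched grids are an error.
    """
    wl = reflectance.wavelengths
    curves = [illuminant, *camera] + ([filter_curve] if filter_curve else [])
    for c in curves:
        if not np.array_equal(c.wavelengths, wl):
            raise SpectralError("all curves must share the reflectance grid")
    t = filter_curve.values if filter_curve is not None else 1.0
    out = []
    for s in camera:
        num = np.trapezoid(reflectance.values * illuminant.values * s.values * t, wl)
        den = np.trapezoid(illuminant.values * s.values, wl)
        out.append(max(0, min(255, _round_half_away(255.0 * num / den))))
    return tuple(out)
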