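"""Spectral front end: Lorentzian peak fits and relative responses.

Near-infrared emission of semiconducting carbon nanotubes comes in
narrow chirality-specific bands; each (suspension, chirality) pair acts
as an independent sensor channel. The peak in a fixed wavelength window
is fitted with a Lorentzian line shape; the relative response of a
sensor to an analyte is the fractional change of the fitted peak height
against the baseline (analyte-free) measurement, ΔI/I₀.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .errors import FitError, ValidationError

__all__ = [
    "Spectrum",
    "LorentzianFit",
    "ChiralityWindow",
    "DEFAULT_WINDOWS",
    "lorentzian",
    "fit_lorentzian_peak",
    "relative_response",
    "extract_response_table",
]


@dataclass(frozen=True)
class Spectrum:
    """One emission spectrum on a strictly increasing wavelength grid (nm)."""

    wavelength_nm: np.ndarray
    intensity: np.ndarray
    excitation_nm: float
    sensor_id: str
    analyte: str  # analyte name, or "baseline" for the analyte-free reference
    replicate: int

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelength_nm, dtype=float)
        it = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "wavelength_nm", wl)
        object.__setattr__(self, "intensity", it)
        if wl.ndim != 1 or it.ndim != 1 or wl.shape != it.shape:
            raise ValidationError("wavelength and intensity must be equal-length 1D")
        if wl.size < 2 or not np.all(np.diff(wl) > 0):
            raise ValidationError("wavelength grid must be strictly increasing")
        if not (np.isfinite(wl).all() and np.isfinite(it).all()):
            raise ValidationError("spectrum contains non-finite values")

    @property
    def is_baseline(self) -> bool:
        return self.analyte == "baseline"


@dataclass(frozen=True)
class ChiralityWindow:
    """Wavelength window expected to contain one chirality's emission peak."""

    chirality: str
    excitation_nm: float
    lo_nm: float
    hi_nm: float

    def __post_init__(self) -> None:
        if not self.lo_nm < self.hi_nm:
            raise ValidationError("window requires lo_nm < hi_nm")


#: Default emission windows bracketing the printed peak maxima of the
#: (6,5), (7,5) and (9,4) chiralities (λem ≈ 995, 1050, 1130 nm at
#: λex = 570, 660, 730 nm). User-overridable.
DEFAULT_WINDOWS = [
    ChiralityWindow("(6,5)", 570.0, 950.0, 1040.0),
    ChiralityWindow("(7,5)", 660.0, 1010.0, 1090.0),
    ChiralityWindow("(9,4)", 730.0, 1090.0, 1170.0),
]


@dataclass(frozen=True)
class LorentzianFit:
    """Least-squares Lorentzian fit: height parameterization plus a
    constant baseline. ``half_width_nm`` is the half-width at
    half-maximum γ, so the FWHM equals 2γ."""

    center_nm: float
    half_width_nm: float
    amplitude: float
    baseline: float
    residual_norm: float

    def __post_init__(self) -> None:
        if self.half_width_nm <= 0:
            raise ValidationError("half-width γ must be > 0")
        if self.amplitude < 0:
            raise ValidationError("amplitude must be ≥ 0")

    @property
    def fwhm_nm(self) -> float:
        return 2.0 * self.half_width_nm

    def __call__(self, wavelength_nm: np.ndarray) -> np.ndarray:
        return lorentzian(np.asarray(wavelength_nm, float), self.center_nm,
                          self.half_width_nm, self.amplitude, self.baseline)


def lorentzian(lam: np.ndarray, center: float, gamma: float,
               amplitude: float, baseline: float) -> np.ndarray:
    """I(λ) = baseline + amplitude · γ² / ((λ − λ₀)² + γ²)."""
    return baseline + amplitude * gamma**2 / ((lam - center) ** 2 + gamma**2)


def fit_lorentzian_peak(spectrum: Spectrum,
                        window: ChiralityWindow) -> LorentzianFit:
    """Least-squares Lorentzian fit restricted to the window.

    Initial guesses: λ₀ at the window argmax, amplitude = max − min,
    γ = quarter window width, baseline = window minimum. The center is
    constrained to the window and γ, amplitude to be positive.
    """
    mask = (spectrum.wavelength_nm >= window.lo_nm) & (
        spectrum.wavelength_nm <= window.hi_nm)
    lam = spectrum.wavelength_nm[mask]
    inten = spectrum.intensity[mask]
    if lam.size < 8:
        raise ValidationError(
            f"window [{window.lo_nm}, {window.hi_nm}] nm overlaps only "
            f"{lam.size} grid points (need ≥ 8)"
        )
    p0 = [
        float(lam[np.argmax(inten)]),
        0.25 * (window.hi_nm - window.lo_nm),
        float(inten.max() - inten.min()),
        float(inten.min()),
    ]
    bounds = ([window.lo_nm, 1e-9, 0.0, -np.inf],
              [window.hi_nm, np.inf, np.inf, np.inf])
    try:
        popt, _ = curve_fit(
            lambda x, c, g, a, b: lorentzian(x, c, g, a, b),
            lam, inten, p0=p0, bounds=bounds, maxfev=20000)
    except (RuntimeError, ValueError) as exc:
        raise FitError(
            f"Lorentzian fit failed for sensor {spectrum.sensor_id!r} "
            f"({spectrum.analyte}, rep {spectrum.replicate}) in window "
            f"{window.chirality}: {exc}"
        ) from exc
    resid = inten - lorentzian(lam, *popt)
    return LorentzianFit(center_nm=float(popt[0]), half_width_nm=float(popt[1]),
                         amplitude=float(popt[2]), baseline=float(popt[3]),
                         residual_norm=float(np.linalg.norm(resid)))


def relative_response(fit_analyte: LorentzianFit,
                      fit_baseline: LorentzianFit) -> float:
    """Relative intensity change ΔI/I₀ = (I − I₀)/I₀ of fitted peak heights.

    Positive values are turn-on responses, negative turn-off (quenching).
    """
    if fit_baseline.amplitude <= 0:
        raise ValidationError("degenerate baseline: fitted amplitude ≤ 0")
    return (fit_analyte.amplitude - fit_baseline.amplitude) / fit_baseline.amplitude


def extract_response_table(spectra: Iterable[Spectrum],
                           windows: Sequence[ChiralityWindow] | None = None):
    """Fit every spectrum in its chirality window and assemble the
    ResponseTable: one column per (suspension, chirality) sensor, one row
    per (analyte, replicate).

    Spectra are matched to windows by excitation wavelength; every
    (sensor, replicate, window) needs exactly one baseline spectrum.
    """
    from .core import ResponseTable
    import pandas as pd

    windows = list(windows) if windows is not None else list(DEFAULT_WINDOWS)
    spectra = list(spectra)
    if not spectra:
        raise ValidationError("empty spectra set")
    by_exc = {w.excitation_nm: w for w in windows}

    baselines: dict[tuple[str, int, str], LorentzianFit] = {}
    responses: dict[tuple[str, int], dict[str, float]] = {}
    fits: list[tuple[Spectrum, ChiralityWindow, LorentzianFit]] = []
    for sp in spectra:
        w = by_exc.get(sp.excitation_nm)
        if w is None:
            raise ValidationError(
                f"no window matches excitation {sp.excitation_nm} nm "
                f"(sensor {sp.sensor_id!r})"
            )
        fit = fit_lorentzian_peak(sp, w)
        if sp.is_baseline:
            key = (sp.sensor_id, sp.replicate, w.chirality)
            if key in baselines:
                raise ValidationError(f"duplicate baseline spectrum for {key}")
            baselines[key] = fit
        else:
            fits.append((sp, w, fit))

    seen: set[tuple[str, str, int, str]] = set()
    for sp, w, fit in fits:
        base = baselines.get((sp.sensor_id, sp.replicate, w.chirality))
        if base is None:
            raise ValidationError(
                f"missing baseline spectrum for sensor {sp.sensor_id!r}, "
                f"replicate {sp.replicate}, window {w.chirality}"
            )
        key = (sp.sensor_id, sp.analyte, sp.replicate, w.chirality)
        if key in seen:
            raise ValidationError(f"duplicate spectrum for {key}")
        seen.add(key)
        col = f"{sp.sensor_id}-{w.chirality}"
        responses.setdefault((sp.analyte, sp.replicate), {})[col] = (
            relative_response(fit, base))

    if not responses:
        raise ValidationError("spectra set contains no analyte measurements")
    idx = pd.MultiIndex.from_tuples(sorted(responses),
                                    names=["analyte", "replicate"])
    df = pd.DataFrame([responses[k] for k in sorted(responses)], index=idx)
    df = df.reindex(sorted(df.columns), axis=1)
    if df.isna().any().any():
        missing = [(str(i), c) for c in df.columns for i in df.index[df[c].isna()]]
        raise ValidationError(f"incomplete screen; missing cells: {missing[:10]}")
    return ResponseTable(df)
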