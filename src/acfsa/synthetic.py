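"""Synthetic fingerprint screens and emission spectra.

Emulates the statistical structure of a 30-sensor fluorescence screen:
10 peptide corona phases (5 sequences, each plain and photo-oxidized)
× 3 nanotube chiralities, responding to 5 metal-ion analytes measured
in quintuplicate with ~3% standard deviation in ΔI/I₀ units. Response
profiles span turn-on (+) and turn-off (−) signs, and inter-analyte
separation is enforced so that the clean screen is perfectly clusterable
— the regime the selection algorithm is designed for. Stress variants
(more replicates, inflated noise) probe graceful degradation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .core import ResponseTable
from .errors import ValidationError
from .spectra import ChiralityWindow, Spectrum, lorentzian

__all__ = [
    "CORONA_PHASES",
    "CHIRALITIES",
    "ANALYTES",
    "SyntheticSpec",
    "paper_like_spec",
    "stress_spec",
    "generate_response_table",
    "generate_spectrum",
    "spectra_from_responses",
]

PEPTIDES = ("Arg", "Glu", "Lys", "Cys", "Gly")
CORONA_PHASES = tuple(p for pep in PEPTIDES for p in (pep, pep + "Ox"))
CHIRALITIES = ("(6,5)", "(7,5)", "(9,4)")
ANALYTES = ("Cr3+", "Cu2+", "Hg2+", "Ni2+", "Pb2+")

#: emission peak center and half-width used for synthetic spectra, per chirality
EMISSION_PEAKS = {"(6,5)": 995.0, "(7,5)": 1050.0, "(9,4)": 1130.0}
DEFAULT_GAMMA_NM = 15.0

RESPONSE_RANGE = (-0.95, 0.95)  # physical guard: ΔI/I₀ cannot reach −1
MIN_LINF_SEPARATION = 0.3  # 10× the default 0.03 std; audited, redraw on failure

# Low-rank structure of the mean response matrix (see docs/methods.md):
# a dominant analyte axis (mirroring the strongly PC1-dominated variance
# of real screens), a weak secondary axis, and idiosyncratic residuals.
_MAIN_AXIS_HALF_RANGE = 1.1
_LOADING_MAGNITUDE = (0.25, 0.55)
_SECONDARY_AXIS_STD = 0.07
_RESIDUAL_STD = 0.035


def default_sensor_ids() -> list[str]:
    """30 sensor ids: one per (corona phase, chirality)."""
    return [f"{c}-{ch}" for c in CORONA_PHASES for ch in CHIRALITIES]


@dataclass(frozen=True)
class SyntheticSpec:
    """Blueprint of a synthetic screen.

    ``mean_matrix`` is sensors × analytes of true mean responses ΔI/I₀;
    each generated replicate adds independent Normal(0, std) noise.
    ``std`` is absolute, in the same dimensionless units.
    """

    mean_matrix: pd.DataFrame
    std: float | np.ndarray = 0.03
    n_replicates: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.std) < 0):
            raise ValidationError("std must be ≥ 0")
        if self.n_replicates < 1:
            raise ValidationError("n_replicates must be ≥ 1")

    @property
    def sensor_ids(self) -> list[str]:
        return [str(s) for s in self.mean_matrix.index]

    @property
    def analytes(self) -> list[str]:
        return [str(a) for a in self.mean_matrix.columns]


def _draw_mean_matrix(rng: np.random.Generator, n_sensors: int,
                      n_analytes: int) -> np.ndarray:
    """One draw of the low-rank mean scheme M = u vᵀ + w zᵀ + residual.

    ``v`` places the analytes on a dominant response axis (equally spaced
    scores, seeded permutation and jitter); every sensor loads on it with
    magnitude bounded away from zero and a random sign, so responses span
    turn-on and turn-off and any sensor subset preserves the analyte
    ordering. A weak secondary axis and per-entry residuals add the
    sensor-specific fingerprint detail that the chi-squared ranking
    discriminates on.
    """
    v = np.linspace(-_MAIN_AXIS_HALF_RANGE, _MAIN_AXIS_HALF_RANGE, n_analytes)
    v = rng.permutation(v) + rng.uniform(-0.05, 0.05, n_analytes)
    z = rng.permutation(np.linspace(-1.0, 1.0, n_analytes))
    u = rng.uniform(*_LOADING_MAGNITUDE, n_sensors) * rng.choice(
        [-1.0, 1.0], n_sensors)
    w = rng.normal(0.0, _SECONDARY_AXIS_STD, n_sensors)
    r = rng.normal(0.0, _RESIDUAL_STD, (n_sensors, n_analytes))
    M = np.outer(u, v) + np.outer(w, z) + r
    return np.clip(M, *RESPONSE_RANGE)


def paper_like_spec(seed: int = 0) -> SyntheticSpec:
    """Default screen: 30 sensors × 5 analytes × 5 replicates, std 0.03.

    The mean matrix is drawn once (seeded) from the low-rank scheme of
    :func:`_draw_mean_matrix` and audited: if any two analyte profiles
    come within L∞ distance 0.3 (10σ) of each other the whole matrix is
    redrawn, so the clean screen is separable by construction.
    """
    sensors = default_sensor_ids()
    for attempt in range(100):
        rng = np.random.default_rng([seed, attempt])
        M = _draw_mean_matrix(rng, len(sensors), len(ANALYTES))
        diffs = [np.max(np.abs(M[:, i] - M[:, j]))
                 for i in range(M.shape[1]) for j in range(i + 1, M.shape[1])]
        if min(diffs) >= MIN_LINF_SEPARATION:
            break
    else:  # pragma: no cover - adjacent axis scores alone separate by ≥ 0.26
        raise RuntimeError("could not draw separated analyte profiles")
    Mdf = pd.DataFrame(M, index=sensors, columns=list(ANALYTES))
    return SyntheticSpec(mean_matrix=Mdf, std=0.03, n_replicates=5, seed=seed)


def stress_spec(spec: SyntheticSpec, n_replicates: int = 50,
                std_multiplier: float = 4.0) -> SyntheticSpec:
    """Stress variant: more replicates, inflated noise (default 50 reps, 4× std)."""
    return replace(spec, n_replicates=n_replicates,
                   std=np.asarray(spec.std) * std_multiplier)


def generate_response_table(spec: SyntheticSpec,
                            seed: int | None = None) -> ResponseTable:
    """Draw a complete screen: entries ~ Normal(M[s, a], std) i.i.d.

    ``seed`` defaults to ``spec.seed``; the same seed reproduces the
    table bit-for-bit.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    M = spec.mean_matrix.to_numpy(dtype=float)  # sensors × analytes
    n_sensors, n_analytes = M.shape
    std = np.broadcast_to(np.asarray(spec.std, dtype=float), M.shape)
    rows, analytes, reps = [], [], []
    for j, analyte in enumerate(spec.analytes):
        noise = rng.normal(0.0, 1.0, size=(spec.n_replicates, n_sensors))
        block = M[:, j][None, :] + noise * std[:, j][None, :]
        for r in range(spec.n_replicates):
            rows.append(block[r])
            analytes.append(analyte)
            reps.append(r + 1)
    return ResponseTable.from_arrays(np.vstack(rows), spec.sensor_ids,
                                     analytes, reps)


def generate_spectrum(
    peaks: list[tuple[float, float, float]],
    baseline: float = 0.0,
    noise_std: float = 0.0,
    grid: np.ndarray | None = None,
    seed: int = 0,
    sensor_id: str = "synthetic",
    analyte: str = "baseline",
    replicate: int = 1,
    excitation_nm: float = 570.0,
) -> Spectrum:
    """Sum of Lorentzian peaks + constant baseline + seeded Gaussian noise.

    ``peaks`` is a list of (center_nm, half_width_nm, amplitude) triples.
    """
    if grid is None:
        grid = np.arange(900.0, 1250.0, 1.0)
    grid = np.asarray(grid, dtype=float)
    intensity = np.full_like(grid, float(baseline))
    for center, gamma, amplitude in peaks:
        if gamma <= 0:
            raise ValidationError("half-width γ must be > 0")
        intensity = intensity + lorentzian(grid, center, gamma, amplitude, 0.0)
    if noise_std > 0:
        rng = np.random.default_rng(seed)
        intensity = intensity + rng.normal(0.0, noise_std, size=grid.shape)
    return Spectrum(wavelength_nm=grid, intensity=intensity,
                    excitation_nm=excitation_nm, sensor_id=sensor_id,
                    analyte=analyte, replicate=replicate)


def spectra_from_responses(
    table: ResponseTable,
    windows: list[ChiralityWindow],
    base_amplitude: float = 1.0,
    gamma_nm: float = DEFAULT_GAMMA_NM,
    baseline: float = 0.0,
    noise_std: float = 0.0,
    seed: int = 0,
) -> list[Spectrum]:
    """Emit a spectra set whose fitted responses reproduce ``table``.

    Sensor ids must follow the ``"<suspension>-<chirality>"`` convention
    with one chirality per window. For every (suspension, window,
    replicate) a baseline spectrum of amplitude ``base_amplitude`` is
    produced, plus per-analyte spectra of amplitude
    ``base_amplitude · (1 + ΔI/I₀)``.
    """
    by_chir = {w.chirality: w for w in windows}
    spectra: list[Spectrum] = []
    counter = 0
    reps = sorted(set(int(r) for r in table.replicate_index))
    for sensor in table.sensor_ids:
        suspension, _, chirality = sensor.rpartition("-")
        if not suspension or chirality not in by_chir:
            raise ValidationError(
                f"sensor id {sensor!r} does not end in a known chirality"
            )
        w = by_chir[chirality]
        center = EMISSION_PEAKS.get(chirality, 0.5 * (w.lo_nm + w.hi_nm))
        for rep in reps:
            spectra.append(generate_spectrum(
                [(center, gamma_nm, base_amplitude)], baseline=baseline,
                noise_std=noise_std, seed=seed + counter,
                sensor_id=suspension, analyte="baseline", replicate=rep,
                excitation_nm=w.excitation_nm))
            counter += 1
        for (analyte, rep), value in table.data[sensor].items():
            amp = base_amplitude * (1.0 + float(value))
            if amp <= 0:
                raise ValidationError(
                    f"response {value} for {sensor!r} implies non-positive "
                    "intensity; cannot be realized as a spectrum"
                )
            spectra.append(generate_spectrum(
                [(center, gamma_nm, amp)], baseline=baseline,
                noise_std=noise_std, seed=seed + counter,
                sensor_id=suspension, analyte=str(analyte),
                replicate=int(rep), excitation_nm=w.excitation_nm))
            counter += 1
    return spectra
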