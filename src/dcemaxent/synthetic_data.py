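"""Synthetic DCE-MRI study generation with known ground truth.

The study design emulated here is a breast DCE-MRI protocol: per patient,
46 dynamic frames acquired every 11.9 s after contrast injection, giving a
plasma (arterial input function, AIF) curve Cp(t) and a tissue curve
Ctis(t). Tissue curves are generated from the AIF through the
two-compartment exchange model with per-patient rate constants (K1, K2) and
additive homoscedastic Gaussian noise, so every downstream estimator can be
tested against known truth.

Times are handled in **minutes** internally (rate constants are 1/min);
grids are specified in seconds at the interface, matching how acquisition
protocols are quoted.

The AIF is a scaled Weibull probability density by default — a unimodal
first-pass bolus shape with shape k, scale c (min) and an amplitude in
mM*min (a bare pdf has unit area, not physical concentration) — with a
biexponential washout family available as a comparator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.stats import weibull_min

__all__ = [
    "TimeGrid",
    "ConcentrationTimeSeries",
    "AIFShape",
    "StudyConfig",
    "PatientRecord",
    "generate_aif_curve",
    "generate_tissue_curve",
    "simulate_study",
    "concentration_from_T1",
    "DEFAULT_GRID",
    "DEFAULT_AIF",
]

SECONDS_PER_MINUTE = 60.0


@dataclass(frozen=True)
class TimeGrid:
    """Uniform sampling grid, specified in seconds."""

    start_s: float = 0.0
    interval_s: float = 11.9
    n_points: int = 46

    def __post_init__(self) -> None:
        if self.interval_s <= 0:
            raise ValueError("interval must be positive")
        if self.n_points < 2:
            raise ValueError("a grid needs at least 2 points")

    def times_s(self) -> np.ndarray:
        return self.start_s + self.interval_s * np.arange(self.n_points)

    def times_min(self) -> np.ndarray:
        return self.times_s() / SECONDS_PER_MINUTE


@dataclass
class ConcentrationTimeSeries:
    """One patient's sampled concentration curve: times in minutes, values in mM."""

    patient_id: str
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.size != self.values.size:
            raise ValueError("times and values must have equal length")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("concentrations must be finite")

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class AIFShape:
    """Parametric AIF family.

    ``weibull_scaled``: amplitude * WeibullPDF(t - delay; k, c) — the bolus
    shape the fitted data supports. ``biexponential``: amplitude *
    sum(a_i * exp(-m_i (t - delay))), a literature-style washout comparator.
    All times/scales are in minutes.
    """

    family: Literal["weibull_scaled", "biexponential"] = "weibull_scaled"
    k: float = 3.0
    c: float = 1.8498
    a1: float = 3.99
    a2: float = 4.78
    m1: float = 0.144
    m2: float = 0.0111
    amplitude: float = 1.0
    delay_min: float = 0.0

    def __post_init__(self) -> None:
        if self.family == "weibull_scaled":
            for name in ("k", "c"):
                if getattr(self, name) <= 0:
                    raise ValueError(f"Weibull parameter {name!r} must be positive, got {getattr(self, name)}")
        elif self.family == "biexponential":
            for name in ("a1", "a2", "m1", "m2"):
                if getattr(self, name) <= 0:
                    raise ValueError(f"biexponential parameter {name!r} must be positive, got {getattr(self, name)}")
        else:
            raise ValueError(f"unknown AIF family {self.family!r}")
        if self.amplitude < 0:
            raise ValueError(f"parameter 'amplitude' must be non-negative, got {self.amplitude}")
        if self.delay_min < 0:
            raise ValueError(f"parameter 'delay_min' must be non-negative, got {self.delay_min}")

    def evaluate(self, t_min: np.ndarray) -> np.ndarray:
        t = np.asarray(t_min, dtype=float) - self.delay_min
        out = np.zeros_like(t)
        after = t >= 0
        if self.family == "weibull_scaled":
            out[after] = self.amplitude * weibull_min.pdf(t[after], self.k, scale=self.c)
        else:
            out[after] = self.amplitude * (
                self.a1 * np.exp(-self.m1 * t[after]) + self.a2 * np.exp(-self.m2 * t[after])
            )
        return out


DEFAULT_GRID = TimeGrid()
DEFAULT_AIF = AIFShape()


@dataclass(frozen=True)
class StudyConfig:
    """Layout of a simulated multi-patient study.

    Per-patient K1, K2 are drawn uniformly from the given ranges (1/min).
    ``noise_mode='relative_peak'`` scales the Gaussian noise sd to
    ``noise_sd`` x (noiseless tissue peak) per patient — 5% of peak by
    default; ``'absolute'`` uses ``noise_sd`` in mM directly.
    """

    n_patients: int = 12
    grid: TimeGrid = DEFAULT_GRID
    aif: AIFShape = DEFAULT_AIF
    k1_range: tuple[float, float] = (0.1, 1.1)
    k2_range: tuple[float, float] = (0.01, 0.4)
    noise_sd: float = 0.05
    noise_mode: Literal["relative_peak", "absolute"] = "relative_peak"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        for name in ("k1_range", "k2_range"):
            lo, hi = getattr(self, name)
            if not (0 <= lo <= hi):
                raise ValueError(f"{name} must satisfy 0 <= lo <= hi")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class PatientRecord:
    """One simulated patient: plasma and tissue curves plus true rates."""

    patient_id: str
    cp: ConcentrationTimeSeries
    ctis: ConcentrationTimeSeries
    truth: "KineticParams"


def generate_aif_curve(shape: AIFShape, grid: TimeGrid) -> ConcentrationTimeSeries:
    """Sample the parametric AIF on the grid (non-negative by construction)."""
    return ConcentrationTimeSeries(
        patient_id="aif", times=grid.times_min(), values=shape.evaluate(grid.times_min())
    )


def generate_tissue_curve(
    aif: ConcentrationTimeSeries,
    k: "KineticParams",
    noise_sd: float = 0.0,
    seed: int = 0,
) -> ConcentrationTimeSeries:
    """Tissue curve from the two-compartment convolution plus Gaussian noise.

    The noiseless part is K1 * integral Cp(u) exp(-K2 (t-u)) du on the AIF's
    grid; independent N(0, noise_sd^2) noise is added per sample (no
    clipping — the noise model is unbounded). Reproducible for fixed seed.
    """
    from .kinetics import tissue_response  # local import: kinetics imports this module

    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    clean = tissue_response(aif, k)
    values = clean.values
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, noise_sd, size=values.size)
    return ConcentrationTimeSeries(patient_id=aif.patient_id, times=aif.times.copy(), values=values)


def simulate_study(cfg: StudyConfig) -> list[PatientRecord]:
    """Simulate a multi-patient study with known kinetic ground truth."""
    from .kinetics import KineticParams, tissue_response

    rng = np.random.default_rng(cfg.seed)
    times = cfg.grid.times_min()
    aif_values = cfg.aif.evaluate(times)
    # all truths are drawn before any noise, so the sampled (K1, K2) do not
    # depend on the noise settings
    truths = [
        KineticParams(k1=float(rng.uniform(*cfg.k1_range)), k2=float(rng.uniform(*cfg.k2_range)))
        for _ in range(cfg.n_patients)
    ]
    records: list[PatientRecord] = []
    for i, truth in enumerate(truths):
        pid = f"patient_{i + 1:02d}"
        cp = ConcentrationTimeSeries(patient_id=pid, times=times.copy(), values=aif_values.copy())
        clean = tissue_response(cp, truth)
        if cfg.noise_mode == "relative_peak":
            sd = cfg.noise_sd * float(np.max(clean.values)) if clean.values.size else 0.0
        else:
            sd = cfg.noise_sd
        noisy = clean.values + (rng.normal(0.0, sd, size=len(clean)) if sd > 0 else 0.0)
        ctis = ConcentrationTimeSeries(patient_id=pid, times=times.copy(), values=noisy)
        records.append(PatientRecord(patient_id=pid, cp=cp, ctis=ctis, truth=truth))
    return records


def concentration_from_T1(t1_t: float, t10: float, r1: float = 4.24) -> float:
    """Contrast-agent concentration (mM) from longitudinal relaxation times.

    Ct = (1/r1) (1/T1(t) - 1/T10), with T1(t) the relaxation time during and
    T10 before contrast (s), and r1 the relaxivity of Gd-DTPA in vivo
    (default 4.24 l/s/mmol).
    """
    if t1_t <= 0 or t10 <= 0:
        raise ValueError("relaxation times must be positive")
    if r1 <= 0:
        raise ValueError("relaxivity must be positive")
    return (1.0 / r1) * (1.0 / t1_t - 1.0 / t10)
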