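"""Synthetic diurnal data with known ground truth.

Three generators mirror the three kinds of input the pipeline consumes:

* replicate time-course tables (analyte x treatment x ZT x replicate),
  built from a mean curve mesor + sum_h A_h cos(2 pi h (t - phi_h)/24)
  with multiplicative lognormal replicate noise of unit median, so
  values stay positive and the replicate coefficient of variation equals
  ``noise_cv``;
* bioluminescence traces: polynomial baseline drift plus an
  exponentially damped cosine plus Gaussian counting noise;
* circular peak-phase samples from a von Mises distribution
  (concentration 0 = circular uniform).

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .biolum import BiolumTrace
from .circstats import PhaseSample

HOURS = 24.0


@dataclass(frozen=True)
class ExperimentDesign:
    """Sampling design of a diurnal tissue-harvest experiment."""

    zts: tuple[float, ...] = (0.0, 4.0, 8.0, 12.0, 16.0, 20.0)
    n_per_cell: int = 5
    treatments: tuple[str, ...] = ("control", "alcohol")
    seed: int = 0

    def __post_init__(self):
        zts = tuple(float(z) for z in self.zts)
        if any(b <= a for a, b in zip(zts, zts[1:])):
            raise ValueError("zts must be strictly increasing")
        if any(not (0.0 <= z < HOURS) for z in zts):
            raise ValueError("zts must lie in [0, 24)")
        if self.n_per_cell < 2:
            raise ValueError("n_per_cell must be >= 2")
        object.__setattr__(self, "zts", zts)


@dataclass(frozen=True)
class RhythmParams:
    """Ground-truth rhythm of one analyte under one treatment.

    harmonics: tuples (order h, amplitude A_h >= 0, acrophase phi_h in
    hours); the mean curve must stay positive over the cycle.
    """

    mesor: float
    harmonics: tuple[tuple[int, float, float], ...] = ()
    base_period: float = 24.0
    noise_cv: float = 0.0

    def __post_init__(self):
        if self.mesor <= 0:
            raise ValueError("mesor must be positive")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        harmonics = tuple((int(h), float(a), float(phi)) for h, a, phi in self.harmonics)
        if any(a < 0 for _, a, _ in harmonics):
            raise ValueError("harmonic amplitudes must be >= 0")
        object.__setattr__(self, "harmonics", harmonics)
        grid = np.arange(0.0, self.base_period, 0.01)
        if np.any(self.mean_curve(grid) <= 0):
            raise ValueError("mean curve must stay positive over the cycle")

    def mean_curve(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        omega = 2.0 * np.pi / self.base_period
        y = np.full(t.shape, float(self.mesor))
        for h, a, phi in self.harmonics:
            y = y + a * np.cos(omega * h * (t - phi))
        return y


@dataclass(frozen=True)
class BiolumParams:
    """Ground truth for a damped, drifting reporter trace."""

    start_zt: float = 4.0
    sampling_interval: float = 10.0  # minutes
    duration: float = 96.0  # hours
    period: float = 24.0
    peak_zt: float = 11.0
    initial_amplitude: float = 100.0
    damping_rate: float = 0.0  # per hour
    baseline_drift: tuple[float, ...] = (0.0,)  # polynomial coeffs, ascending
    noise_sd: float = 0.0

    def __post_init__(self):
        if self.duration < 3.0 * self.period:
            raise ValueError("duration must cover >= 3 periods for a defined period estimate")
        if abs(60.0 / self.sampling_interval - round(60.0 / self.sampling_interval)) > 1e-9:
            raise ValueError("sampling_interval must divide 60 minutes")


@dataclass(frozen=True)
class PhaseSampleParams:
    """von Mises peak-phase sample; concentration 0 gives circular uniform."""

    n: int
    mean_phase: float = 11.0
    concentration: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.concentration < 0:
            raise ValueError("concentration (kappa) must be >= 0")


def _lognormal_sigma(cv: float) -> float:
    return float(np.sqrt(np.log1p(cv * cv)))


def simulate_timecourse(
    design: ExperimentDesign,
    params: dict[tuple[str, str], RhythmParams],
) -> pd.DataFrame:
    """Long-format table `analyte,treatment,zt,replicate,value`.

    Every analyte appearing in ``params`` must have an entry for every
    treatment in the design.  Replicate values are the mean curve times
    unit-median lognormal noise, hence strictly positive.
    """
    analytes = sorted({a for a, _ in params})
    for analyte in analytes:
        for treatment in design.treatments:
            if (analyte, treatment) not in params:
                raise KeyError(f"missing RhythmParams for ({analyte!r}, {treatment!r})")
    rng = np.random.default_rng(design.seed)
    zts = np.asarray(design.zts)
    frames = []
    for analyte in analytes:
        for treatment in design.treatments:
            p = params[(analyte, treatment)]
            mean = p.mean_curve(zts)
            noise = rng.lognormal(0.0, _lognormal_sigma(p.noise_cv), size=(zts.size, design.n_per_cell))
            values = mean[:, None] * noise
            frames.append(
                pd.DataFrame(
                    {
                        "analyte": analyte,
                        "treatment": treatment,
                        "zt": np.repeat(zts, design.n_per_cell),
                        "replicate": np.tile(np.arange(1, design.n_per_cell + 1), zts.size),
                        "value": values.ravel(),
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def simulate_biolum(params: BiolumParams, seed: int = 0) -> BiolumTrace:
    """Damped cosine + polynomial drift + Gaussian noise, 10-min sampling by default."""
    dt = params.sampling_interval / 60.0
    times = np.arange(0.0, params.duration + dt / 2, dt)
    drift = np.polynomial.polynomial.polyval(times, np.asarray(params.baseline_drift, float))
    osc = (
        params.initial_amplitude
        * np.exp(-params.damping_rate * times)
        * np.cos(2.0 * np.pi * (times + params.start_zt - params.peak_zt) / params.period)
    )
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, params.noise_sd, size=times.size) if params.noise_sd > 0 else 0.0
    return BiolumTrace(start_zt=params.start_zt, times=times, counts=drift + osc + noise)


def simulate_phase_sample(params: PhaseSampleParams, group: str = "sample") -> PhaseSample:
    """n peak phases in [0, 24); kappa = 0 draws from the circular uniform."""
    rng = np.random.default_rng(params.seed)
    if params.concentration == 0:
        phases = rng.uniform(0.0, HOURS, size=params.n)
    else:
        mu = 2.0 * np.pi * params.mean_phase / HOURS
        angles = rng.vonmises(mu, params.concentration, size=params.n)
        phases = (angles * HOURS / (2.0 * np.pi)) % HOURS
    return PhaseSample(group=group, phases=phases)
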