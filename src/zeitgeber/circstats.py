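"""Circular statistics for peak-phase samples on the 24-h clock face.

Phases are stored in hours on [0, 24) and converted to radians
(2*pi/24 per hour) internally.  Implements the circular mean with
resultant length r, the Rayleigh test of uniformity with the standard
finite-n corrected p-value, and the Mardia-Watson-Wheeler (uniform
scores) two-sample test with an exact/sampled permutation option for
small groups.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import comb
from typing import Sequence

import numpy as np
from scipy import stats

HOURS = 24.0
_H2R = 2.0 * np.pi / HOURS


def hours_to_radians(phases_h: np.ndarray) -> np.ndarray:
    return np.asarray(phases_h, dtype=float) * _H2R


def radians_to_hours(angles: np.ndarray) -> np.ndarray:
    h = (np.asarray(angles, dtype=float) / _H2R) % HOURS
    return np.where(h >= HOURS, h - HOURS, h)  # guard float rounding at the wrap


@dataclass(frozen=True)
class PhaseSample:
    """A labelled sample of peak phases in hours mod 24."""

    group: str
    phases: np.ndarray

    def __post_init__(self):
        phases = np.asarray(self.phases, dtype=float) % HOURS
        if phases.size < 1:
            raise ValueError("PhaseSample requires n >= 1")
        object.__setattr__(self, "phases", phases)

    @property
    def n(self) -> int:
        return self.phases.size


@dataclass(frozen=True)
class CircTestResult:
    """Outcome of a circular hypothesis test."""

    name: str
    statistic: float
    p_value: float
    n: tuple[int, ...]
    mean_phase: float | None = None
    r: float | None = None
    extra: dict = field(default_factory=dict)


def circular_mean_r(sample: PhaseSample | Sequence[float]) -> tuple[float, float]:
    """Circular mean phase (hours) and resultant length r in [0, 1].

    The mean is the argument of the resultant of unit vectors at each
    phase angle; r is its magnitude divided by n.  For r == 0 the mean
    direction is undefined and NaN is returned.
    """
    phases = sample.phases if isinstance(sample, PhaseSample) else np.asarray(sample, float)
    angles = hours_to_radians(phases)
    z = np.exp(1j * angles).sum()
    r = float(np.abs(z)) / angles.size
    if r < 1e-12:
        return float("nan"), 0.0
    return float(radians_to_hours(np.angle(z))), r


def _rayleigh_p(n: int, r: float) -> float:
    """Finite-n corrected Rayleigh p-value (Zar's approximation)."""
    big_r = n * r
    z = n * r * r
    p = np.exp(np.sqrt(1.0 + 4.0 * n + 4.0 * (n * n - big_r * big_r)) - (1.0 + 2.0 * n))
    return float(min(1.0, p)) if np.isfinite(p) else float(np.exp(-z))


def rayleigh_test(
    sample: PhaseSample,
    n_mc: int | None = None,
    seed: int | None = None,
) -> CircTestResult:
    """Rayleigh test of circular uniformity.

    The statistic is z = n * r**2.  The p-value uses the standard
    finite-n corrected approximation; with ``n_mc`` set, a Monte-Carlo
    p-value under the uniform null (recommended for n < 10) is added to
    ``extra['p_mc']``.
    """
    if sample.n < 2:
        raise ValueError("Rayleigh test requires n >= 2")
    mean_phase, r = circular_mean_r(sample)
    n = sample.n
    z = n * r * r
    p = _rayleigh_p(n, r)
    extra: dict = {}
    if n_mc is not None:
        extra["p_mc"] = rayleigh_mc_pvalue(n, r, n_mc, seed=seed)
    return CircTestResult("rayleigh", float(z), p, (n,), mean_phase, r, extra)


def rayleigh_mc_pvalue(n: int, r_obs: float, n_draws: int, seed: int | None = None) -> float:
    """Monte-Carlo null P(r >= r_obs) for n uniform phases (vectorised, chunked)."""
    rng = np.random.default_rng(seed)
    exceed = 0
    done = 0
    chunk = max(1, min(n_draws, 4_000_000 // max(n, 1)))
    while done < n_draws:
        m = min(chunk, n_draws - done)
        theta = rng.uniform(0.0, 2.0 * np.pi, size=(m, n))
        r_null = np.abs(np.exp(1j * theta).sum(axis=1)) / n
        exceed += int(np.count_nonzero(r_null >= r_obs - 1e-12))
        done += m
    return exceed / n_draws


def _uniform_scores(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Cosine/sine of the uniform scores of the pooled sample ranks.

    Ties get mid-rank (average) scores.  Returns (cos_beta, sin_beta)
    over the pooled sample, ordered group-a first.
    """
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)  # average ranks for ties
    beta = 2.0 * np.pi * ranks / pooled.size
    return np.cos(beta), np.sin(beta)


def _mww_stat(cos_b: np.ndarray, sin_b: np.ndarray, idx_a: np.ndarray, n1: int, n2: int) -> float:
    c1 = cos_b[idx_a].sum()
    s1 = sin_b[idx_a].sum()
    # Over the full circle the pooled scores sum to ~0 only in the tie-free
    # case; compute group 2 sums explicitly to stay exact under ties.
    c2 = cos_b.sum() - c1
    s2 = sin_b.sum() - s1
    return 2.0 * ((c1 * c1 + s1 * s1) / n1 + (c2 * c2 + s2 * s2) / n2)


def mww_test(
    a: PhaseSample,
    b: PhaseSample,
    method: str = "auto",
    n_perm: int = 9999,
    seed: int | None = 0,
    exhaustive_limit: int = 20000,
) -> CircTestResult:
    """Mardia-Watson-Wheeler two-sample uniform-scores test.

    W = 2 * sum_j (C_j^2 + S_j^2) / n_j where C_j, S_j are the cosine and
    sine sums of the uniform scores of group j's pooled-sample ranks.
    ``method``: "asymptotic" (chi-square, 2 df), "permutation", or "auto"
    (permutation when min(n1, n2) < 10).  Exhaustive enumeration of group
    assignments is used when C(n1+n2, n1) <= ``exhaustive_limit``.
    """
    if a.n < 2 or b.n < 2:
        raise ValueError("MWW test requires n >= 2 in each group")
    pooled = np.concatenate([a.phases, b.phases])
    if np.allclose(pooled, pooled[0]):
        raise ValueError("MWW test undefined: all observations identical")
    n1, n2 = a.n, b.n
    cos_b, sin_b = _uniform_scores(a.phases, b.phases)
    idx_obs = np.arange(n1)
    w_obs = _mww_stat(cos_b, sin_b, idx_obs, n1, n2)
    p_asym = float(stats.chi2.sf(w_obs, df=2))

    if method == "auto":
        method = "permutation" if min(n1, n2) < 10 else "asymptotic"

    extra: dict = {"p_asymptotic": p_asym}
    if method == "asymptotic":
        p = p_asym
    elif method == "permutation":
        total = n1 + n2
        n_comb = comb(total, n1)
        tol = 1e-9
        if n_comb <= exhaustive_limit:
            ge = 0
            for combo in itertools.combinations(range(total), n1):
                if _mww_stat(cos_b, sin_b, np.array(combo), n1, n2) >= w_obs - tol:
                    ge += 1
            p = ge / n_comb
            extra["n_perm"] = n_comb
            extra["exhaustive"] = True
        else:
            rng = np.random.default_rng(seed)
            ge = 0
            for _ in range(n_perm):
                idx = rng.permutation(total)[:n1]
                if _mww_stat(cos_b, sin_b, idx, n1, n2) >= w_obs - tol:
                    ge += 1
            p = (1 + ge) / (n_perm + 1)
            extra["n_perm"] = n_perm
            extra["exhaustive"] = False
        extra["p_permutation"] = p
    else:
        raise ValueError(f"unknown method {method!r}")

    return CircTestResult("mardia-watson-wheeler", float(w_obs), float(p), (n1, n2), extra=extra)


def phase_map_plot(samples: Sequence[PhaseSample], path: str) -> None:
    """Polar phase-distribution plot: one dot per phase, mean-vector arrow per group."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(subplot_kw={"projection": "polar"})
    ax.set_theta_zero_location("N")
    ax.set_theta_direction(-1)
    for sample in samples:
        angles = hours_to_radians(sample.phases)
        ax.plot(angles, np.ones_like(angles), "o", alpha=0.6, label=sample.group)
        mean_phase, r = circular_mean_r(sample)
        if np.isfinite(mean_phase):
            ax.annotate(
                "",
                xy=(mean_phase * _H2R, r),
                xytext=(0.0, 0.0),
                arrowprops={"arrowstyle": "-|>", "lw": 2},
            )
    ax.set_xticks(np.arange(0, 2 * np.pi, np.pi / 6))
    ax.set_xticklabels([f"ZT{h}" for h in range(0, 24, 2)])
    ax.set_yticklabels([])
    ax.legend(loc="lower left", bbox_to_anchor=(1.0, 0.0))
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
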