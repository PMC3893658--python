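"""Harmonic-regression (cosinor) rhythm fitting with a center-of-gravity phase.

The model for a 24-h entrained profile is

    y(t) = m + sum_{h=1..H} a_h cos(2 pi h t / 24) + b_h sin(2 pi h t / 24)

fitted by unweighted least squares to individual replicate observations.
The fundamental (H = 1) is kept only if an F-test against the
intercept-only model rejects at ``alpha``; each additional harmonic
(up to two, forward stepwise) is kept only if its incremental F-test
rejects at the same level.  A series failing the fundamental gate yields
:class:`NoFit`.

The phase of a possibly multi-harmonic fit is summarised by its center
of gravity (CG): the argument of the fundamental resultant of the fitted
curve after subtracting its minimum,

    CG = (24 / 2 pi) * arg sum_t w(t) exp(i 2 pi t / 24),
    w(t) = fitted(t) - min fitted,

evaluated on a dense grid over [0, 24).  For a single-harmonic fit the
CG equals the acrophase; for bimodal curves it is a weighted compromise
between the two peaks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats

PERIOD = 24.0
_OMEGA = 2.0 * np.pi / PERIOD
_RSS_TOL = 1e-10


@dataclass(frozen=True)
class TimePointSeries:
    """Replicate observations of one analyte under one treatment across ZT."""

    analyte: str
    treatment: str
    zt: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        zt = np.asarray(self.zt, dtype=float) % PERIOD  # ZT24 double-plot folds onto ZT0
        values = np.asarray(self.values, dtype=float)
        if zt.size != values.size:
            raise ValueError("zt and values must have equal length")
        if np.unique(zt).size < 2:
            raise ValueError("need observations at >= 2 distinct ZTs")
        object.__setattr__(self, "zt", zt)
        object.__setattr__(self, "values", values)

    @classmethod
    def from_timecourse(cls, table: pd.DataFrame, analyte: str, treatment: str) -> "TimePointSeries":
        sub = table[(table["analyte"] == analyte) & (table["treatment"] == treatment)]
        if sub.empty:
            raise KeyError(f"no rows for ({analyte!r}, {treatment!r})")
        return cls(analyte, treatment, sub["zt"].to_numpy(), sub["value"].to_numpy())


@dataclass(frozen=True)
class CosinorFit:
    """A retained harmonic-regression fit (rhythmicity gate passed)."""

    analyte: str
    treatment: str
    mesor: float
    coefficients: tuple[tuple[float, float], ...]  # (a_h, b_h) for h = 1..H
    F_stat: float
    p_value: float
    df: tuple[int, int]
    cg: float
    rhythmic: bool = True

    @property
    def n_harmonics(self) -> int:
        return len(self.coefficients)

    def amplitude(self, h: int) -> float:
        a, b = self.coefficients[h - 1]
        return float(np.hypot(a, b))

    def acrophase(self, h: int) -> float:
        """Peak time of harmonic h in hours, on [0, 24/h)."""
        a, b = self.coefficients[h - 1]
        return float((np.arctan2(b, a) / (_OMEGA * h)) % (PERIOD / h))

    def fitted(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        y = np.full(t.shape, self.mesor)
        for h, (a, b) in enumerate(self.coefficients, start=1):
            y = y + a * np.cos(_OMEGA * h * t) + b * np.sin(_OMEGA * h * t)
        return y


@dataclass(frozen=True)
class NoFit:
    """Marker for a series to which no rhythmic curve could be fitted."""

    analyte: str
    treatment: str
    p_value: float
    rhythmic: bool = False


def _design(t: np.ndarray, n_harmonics: int) -> np.ndarray:
    cols = [np.ones_like(t)]
    for h in range(1, n_harmonics + 1):
        cols.append(np.cos(_OMEGA * h * t))
        cols.append(np.sin(_OMEGA * h * t))
    return np.column_stack(cols)


def _ols(t: np.ndarray, y: np.ndarray, n_harmonics: int) -> tuple[np.ndarray, float]:
    x = _design(t, n_harmonics)
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    return beta, float(resid @ resid)


def _f_test(rss_small: float, rss_big: float, df_extra: int, df_resid: int, scale: float) -> tuple[float, float]:
    """F-test comparing nested fits; returns (F, p) with care near rss = 0."""
    if df_resid < 1:
        raise ValueError("no residual degrees of freedom for F-test")
    if rss_small <= scale:  # nothing left to explain
        return 0.0, 1.0
    if rss_big <= scale:  # perfect fit of the larger model
        return float("inf"), 0.0
    f = ((rss_small - rss_big) / df_extra) / (rss_big / df_resid)
    f = max(f, 0.0)
    return float(f), float(stats.f.sf(f, df_extra, df_resid))


def fit_cosinor(
    series: TimePointSeries,
    alpha: float = 0.05,
    max_extra_harmonics: int = 2,
    cg_grid_step: float = 0.01,
) -> CosinorFit | NoFit:
    """Fit the harmonic-regression model with a stepwise rhythmicity gate.

    Returns a :class:`CosinorFit` with the retained number of harmonics,
    the overall F-test against the intercept-only model, and the CG
    phase; or :class:`NoFit` when the fundamental fails the gate.
    """
    t, y = series.zt, series.values
    n = y.size
    k = np.unique(t).size
    if k < 3 or n - 3 < 1:
        raise ValueError(
            f"insufficient degrees of freedom for ({series.analyte}, {series.treatment}): "
            f"{k} distinct ZTs, {n} observations"
        )
    rss0 = float(np.sum((y - y.mean()) ** 2))
    scale = _RSS_TOL * max(1.0, float(np.sum(y * y)))
    if rss0 <= scale:  # all values identical: nothing to test
        return NoFit(series.analyte, series.treatment, p_value=1.0)

    _, rss1 = _ols(t, y, 1)
    _, p1 = _f_test(rss0, rss1, 2, n - 3, scale)
    if p1 >= alpha:
        return NoFit(series.analyte, series.treatment, p_value=p1)

    n_harm = 1
    rss_cur = rss1
    for h in range(2, 2 + max_extra_harmonics):
        n_par = 1 + 2 * h
        if n_par > k or n - n_par < 1:
            break  # not identifiable / no residual df at this grid
        if rss_cur <= scale:
            break  # current fit already exact
        _, rss_h = _ols(t, y, h)
        _, p_inc = _f_test(rss_cur, rss_h, 2, n - n_par, scale)
        if p_inc < alpha:
            n_harm, rss_cur = h, rss_h
        else:
            break

    beta, rss_final = _ols(t, y, n_harm)
    df_model = 2 * n_harm
    df_resid = n - (1 + df_model)
    f_overall, p_overall = _f_test(rss0, rss_final, df_model, df_resid, scale)

    coeffs = tuple((float(beta[2 * h - 1]), float(beta[2 * h])) for h in range(1, n_harm + 1))
    fit = CosinorFit(
        analyte=series.analyte,
        treatment=series.treatment,
        mesor=float(beta[0]),
        coefficients=coeffs,
        F_stat=f_overall,
        p_value=min(p_overall, p1),
        df=(df_model, df_resid),
        cg=float("nan"),
    )
    cg = center_of_gravity(fit, grid_step=cg_grid_step)
    return CosinorFit(**{**fit.__dict__, "cg": cg})


def center_of_gravity(fit: CosinorFit, grid_step: float = 0.01) -> float:
    """CG phase (hours mod 24) of a fitted curve.

    Weights are the fitted curve minus its minimum on a dense grid over
    [0, 24); the CG is the argument of the weighted fundamental
    resultant.  Raises for an (effectively) flat curve.
    """
    t = np.arange(0.0, PERIOD, grid_step)
    yv = fit.fitted(t)
    w = yv - yv.min()
    span = float(w.max())
    if span <= 1e-12 * max(1.0, float(np.abs(yv).max())):
        raise ValueError("CG undefined for a flat fitted curve")
    z = np.sum(w * np.exp(1j * _OMEGA * t))
    if np.abs(z) <= 1e-12 * np.sum(w):
        raise ValueError("CG undefined: fundamental resultant vanishes")
    cg = float((np.angle(z) / _OMEGA) % PERIOD)
    return 0.0 if cg >= PERIOD else cg  # guard float rounding at the wrap


FIT_TABLE_COLUMNS = [
    "analyte", "treatment", "H", "mesor",
    "amp1", "phi1", "amp2", "phi2", "amp3", "phi3",
    "F", "p", "CG", "rhythmic",
]


def fit_table(
    table: pd.DataFrame,
    alpha: float = 0.05,
    max_extra_harmonics: int = 2,
) -> pd.DataFrame:
    """Fit every (analyte, treatment) profile of a long-format time-course table."""
    rows = []
    pairs = table[["analyte", "treatment"]].drop_duplicates().itertuples(index=False)
    for analyte, treatment in pairs:
        series = TimePointSeries.from_timecourse(table, analyte, treatment)
        res = fit_cosinor(series, alpha=alpha, max_extra_harmonics=max_extra_harmonics)
        row = {c: np.nan for c in FIT_TABLE_COLUMNS}
        row.update(analyte=analyte, treatment=treatment, rhythmic=res.rhythmic, p=res.p_value)
        if isinstance(res, CosinorFit):
            row.update(H=res.n_harmonics, mesor=res.mesor, F=res.F_stat, CG=res.cg)
            for h in range(1, res.n_harmonics + 1):
                row[f"amp{h}"] = res.amplitude(h)
                row[f"phi{h}"] = res.acrophase(h)
        else:
            row["H"] = 0
        rows.append(row)
    return pd.DataFrame(rows, columns=FIT_TABLE_COLUMNS)
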