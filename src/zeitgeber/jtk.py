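"""JTK-style nonparametric rhythm detection and clock-controlled-gene calls.

Each series is scored against a family of cosine templates
cos(2 pi (t - phase) / period) over a circadian period band (20-28 h by
default).  Agreement with a template is Kendall's S = C - D (concordant
minus discordant pairs), taken over pairs at which the template values
differ.  For short series the p-value comes from the exact null
distribution of S given the template's tie pattern, computed by dynamic
programming (the null counts factorise into a convolution of
Mann-Whitney U distributions over the template's tie groups); longer
series use a normal approximation with tie and continuity corrections.

The reported p is the minimum two-sided template p; because the minimum
over templates is anticonservative, a Bonferroni-adjusted p over the
number of distinct templates is also reported and used for q-value
computation.  A clock-controlled gene (CCG) is a series with q below
threshold and best period inside the band; its peak is binned into
day (CT0-11) or night (CT12-23).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

HOURS = 24.0
EXACT_MAX_N = 14


@dataclass(frozen=True)
class RhythmSeries:
    """One analyte's values over an extended (e.g. 48-h) time course."""

    analyte: str
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if times.size != values.size:
            raise ValueError("times and values must have equal length")
        if times.size < 8:
            raise ValueError("rhythm scoring requires >= 8 time points")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)


@dataclass(frozen=True)
class RhythmCall:
    """Outcome of the template scan for one series."""

    analyte: str
    tau: float
    p_value: float          # raw minimum template p
    p_adjusted: float       # Bonferroni over the template family
    best_period: float | None
    best_phase: float | None
    q_value: float | None = None
    is_ccg: bool | None = None
    phase_bin: str | None = None
    n_templates: int = 0


@lru_cache(maxsize=2048)
def _mw_counts(m: int, n: int) -> tuple[float, ...]:
    """Null counts of the Mann-Whitney U statistic between blocks of size m and n.

    Classic recurrence f(u; m, n) = f(u - n; m - 1, n) + f(u; m, n - 1):
    the number of interleavings of the two blocks with exactly u
    cross-block inversions.
    """
    if m == 0 or n == 0:
        return (1.0,)
    a = np.asarray(_mw_counts(m - 1, n))
    b = np.asarray(_mw_counts(m, n - 1))
    out = np.zeros(m * n + 1)
    out[: b.size] += b
    out[n : n + a.size] += a
    return tuple(out)


@lru_cache(maxsize=256)
def kendall_null_pmf(group_sizes: tuple[int, ...]) -> tuple[float, ...]:
    """Exact null pmf of the concordance count C for a template with tie groups.

    The template partitions the N positions into tie groups of the given
    sizes; valid pairs are those across groups (T = sum over group pairs
    of products).  Under the null the data are an exchangeable tie-free
    sequence, and the distribution of C factorises as the convolution of
    Mann-Whitney U null distributions obtained by merging groups one at a
    time (the q-multinomial identity).  Returns pmf over C = 0..T.
    """
    pmf = np.array([1.0])
    n_cur = 0
    for g in group_sizes:
        if n_cur > 0:
            counts = np.asarray(_mw_counts(n_cur, g))
            pmf = np.convolve(pmf, counts / counts.sum())
        n_cur += g
    return tuple(pmf)


def _template_groups(template: np.ndarray) -> tuple[int, ...]:
    _, counts = np.unique(np.round(template, 9), return_counts=True)
    return tuple(int(c) for c in counts)


def _concordance(values: np.ndarray, template: np.ndarray) -> tuple[int, int, int]:
    """(C, D, T): concordant, discordant and template-untied pair counts."""
    dv = values[:, None] - values[None, :]
    dt = template[:, None] - template[None, :]
    upper = np.triu(np.ones(values.size, dtype=bool), k=1)
    untied = upper & (np.abs(dt) > 1e-9)
    prod = dv[untied] * dt[untied]
    c = int(np.count_nonzero(prod > 0))
    d = int(np.count_nonzero(prod < 0))
    return c, d, int(np.count_nonzero(untied))


def _template_pvalue(values: np.ndarray, template: np.ndarray) -> tuple[float, float]:
    """One-sided (positive agreement) p, doubled, for one template; returns (p, tau).

    The phase grid covers the full cycle, so negative correlation with
    one template is positive correlation with its anti-phase partner;
    each template is therefore scored one-sided for positive tau and the
    p doubled for two-sidedness, as in the published scan.
    """
    c, d, t_pairs = _concordance(values, template)
    if t_pairs == 0:
        return 1.0, float("nan")
    s = c - d
    tau = s / t_pairs
    n = values.size
    groups = _template_groups(template)
    if n <= EXACT_MAX_N:
        pmf = np.asarray(kendall_null_pmf(groups))
        # pmf is over C assuming tie-free data; observed C with data ties is
        # conservative (ties drop out of both C and D).
        p1 = float(pmf[c:].sum())
    else:
        var_s = (n * (n - 1) * (2 * n + 5) - sum(g * (g - 1) * (2 * g + 5) for g in groups)) / 18.0
        z = (s - 1.0) / np.sqrt(var_s)
        p1 = float(stats.norm.sf(z))
    return min(1.0, 2.0 * p1), tau


def jtk_score(
    series: RhythmSeries,
    period_min: float = 20.0,
    period_max: float = 28.0,
    period_step: float | None = None,
    phase_step: float | None = None,
) -> RhythmCall:
    """Scan cosine templates over (period, phase) and report the best match.

    Period and phase grids default to the sampling interval.  The call
    carries the raw minimum two-sided p and its Bonferroni adjustment
    over the template count; q-values are attached later (see
    :func:`bh_qvalues` / :func:`jtk_table`).
    """
    t, y = series.times, series.values
    step = float(np.median(np.diff(t)))
    period_step = step if period_step is None else period_step
    phase_step = step if phase_step is None else phase_step

    if np.allclose(y, y[0]):
        return RhythmCall(series.analyte, float("nan"), 1.0, 1.0, None, None)

    best = (np.inf, None, None, float("nan"))  # (p, period, phase, tau)
    n_templates = 0
    periods = np.arange(period_min, period_max + 1e-9, period_step)
    for period in periods:
        for phase in np.arange(0.0, period - 1e-9, phase_step):
            template = np.cos(2.0 * np.pi * (t - phase) / period)
            p, tau = _template_pvalue(y, template)
            n_templates += 1
            if p < best[0] - 1e-15:
                best = (p, float(period), float(phase), tau)
    p_min, period, phase, tau = best
    p_adj = min(1.0, p_min * n_templates)
    return RhythmCall(series.analyte, tau, float(p_min), float(p_adj), period, phase,
                      n_templates=n_templates)


def bh_qvalues(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (order-preserving)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify_ccg(
    call: RhythmCall,
    q_threshold: float = 0.1,
    period_band: tuple[float, float] = (20.0, 28.0),
) -> RhythmCall:
    """Apply the CCG rule (q < threshold and period in band) and phase binning."""
    if call.q_value is None:
        raise ValueError("q_value must be set before classification")
    in_band = (
        call.best_period is not None
        and period_band[0] <= call.best_period <= period_band[1]
    )
    is_ccg = bool(call.q_value < q_threshold and in_band)
    phase_bin = None
    if call.best_phase is not None:
        phase_bin = "day" if (call.best_phase % HOURS) < 12.0 else "night"
    return replace(call, is_ccg=is_ccg, phase_bin=phase_bin)


def jtk_table(
    matrix: pd.DataFrame,
    q_threshold: float = 0.1,
    period_min: float = 20.0,
    period_max: float = 28.0,
) -> pd.DataFrame:
    """Score every row of a series matrix and attach BH q-values and CCG calls.

    ``matrix``: first column analyte labels, remaining columns time-point
    headers such as ``CT0, CT4, ...`` (any numeric suffix is accepted).
    """
    label_col = matrix.columns[0]
    times = np.array([float(str(c).lstrip("CTZTct ")) for c in matrix.columns[1:]])
    calls = []
    for _, row in matrix.iterrows():
        series = RhythmSeries(str(row[label_col]), times, row.iloc[1:].to_numpy(dtype=float))
        calls.append(jtk_score(series, period_min=period_min, period_max=period_max))
    qs = bh_qvalues([c.p_adjusted for c in calls])
    calls = [
        classify_ccg(replace(c, q_value=float(q)), q_threshold, (period_min, period_max))
        for c, q in zip(calls, qs)
    ]
    return pd.DataFrame(
        {
            "analyte": [c.analyte for c in calls],
            "tau": [c.tau for c in calls],
            "p": [c.p_value for c in calls],
            "p_adj": [c.p_adjusted for c in calls],
            "q": [c.q_value for c in calls],
            "period": [c.best_period for c in calls],
            "phase": [c.best_phase for c in calls],
            "is_ccg": [c.is_ccg for c in calls],
            "phase_bin": [c.phase_bin for c in calls],
        }
    )
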