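"""Diurnal differential-expression and metabolite-panel statistics.

Covers the layer around the rhythm fits: normalisation to a reference
analyte (e.g. 18S rRNA), rescaling of profiles relative to the lowest
per-ZT mean, per-time-point Student t-tests (with pre-registered
one-tailed exceptions), fold-change tiering of a screen at one ZT,
Time x Treatment two-way ANOVA with Tukey post-hoc contrasts and an
automatic log/sqrt normality transform, peak-to-trough amplitude ratios,
and phase-cluster summaries of differentially expressed
clock-controlled genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cosinor import TimePointSeries

TIME_COL, TREAT_COL, VALUE_COL = "zt", "treatment", "value"


@dataclass(frozen=True)
class DEGeneRecord:
    """One analyte's differential-expression call at a single ZT.

    fold_change is the alcohol/control ratio of means; magnitude is the
    symmetric fold change (1/fc for down-regulated analytes), matching
    the "down-regulated by x-fold" convention.
    """

    analyte: str
    fold_change: float
    direction: str  # "up" | "down"
    p_value: float
    tier: str | None  # "strong" (|fc| >= 2), "moderate" (1.5 <= |fc| < 2), None

    @property
    def magnitude(self) -> float:
        return self.fold_change if self.fold_change >= 1.0 else 1.0 / self.fold_change


@dataclass(frozen=True)
class AnovaResult:
    """Two-way (Time x Treatment) fixed-effects ANOVA with per-ZT Tukey contrasts."""

    table: pd.DataFrame  # index Time/Treatment/Interaction/Residual; columns sum_sq, df, F, PR(>F)
    tukey_pairs: dict[float, float]  # zt -> Tukey-adjusted p for control vs alcohol
    transform_applied: str  # "none" | "log" | "sqrt"

    def p(self, factor: str) -> float:
        return float(self.table.loc[factor, "PR(>F)"])


@dataclass(frozen=True)
class AmplitudeRatio:
    """Peak-to-trough fold changes of per-ZT means and their alcohol/control ratio."""

    analyte: str
    control_p2t: float
    alcohol_p2t: float
    ratio: float  # rounded half-up to 1 decimal


def round_half_up(x: float, decimals: int = 1) -> float:
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def normalize_to_reference(raw: pd.DataFrame, reference_analyte: str = "18S") -> pd.DataFrame:
    """Divide every value by its own sample's reference-analyte value.

    A 'sample' is a (treatment, zt, replicate) triple.  Reference rows
    are removed from the output.
    """
    ref = raw[raw["analyte"] == reference_analyte]
    if ref.empty:
        raise KeyError(f"reference analyte {reference_analyte!r} not present")
    ref_map = ref.set_index([TREAT_COL, TIME_COL, "replicate"])[VALUE_COL]
    if ref_map.index.has_duplicates:
        raise ValueError("duplicate reference rows per sample")
    out = raw[raw["analyte"] != reference_analyte].copy()
    keys = pd.MultiIndex.from_frame(out[[TREAT_COL, TIME_COL, "replicate"]])
    ref_vals = ref_map.reindex(keys)
    if ref_vals.isna().any():
        missing = keys[ref_vals.isna().to_numpy()][0]
        raise KeyError(f"missing reference value for sample {tuple(missing)}")
    out[VALUE_COL] = out[VALUE_COL].to_numpy() / ref_vals.to_numpy()
    return out.reset_index(drop=True)


def rescale_relative(
    ctrl: TimePointSeries, alc: TimePointSeries
) -> tuple[TimePointSeries, TimePointSeries]:
    """Rescale a control/alcohol pair so the lowest per-ZT mean across both is 1.0."""
    if np.any(ctrl.values <= 0) or np.any(alc.values <= 0):
        raise ValueError("rescale_relative requires positive values")
    mins = []
    for s in (ctrl, alc):
        for z in np.unique(s.zt):
            mins.append(s.values[s.zt == z].mean())
    scale = min(mins)
    return (
        TimePointSeries(ctrl.analyte, ctrl.treatment, ctrl.zt, ctrl.values / scale),
        TimePointSeries(alc.analyte, alc.treatment, alc.zt, alc.values / scale),
    )


def _ttest(x: np.ndarray, y: np.ndarray, equal_var: bool, alternative: str) -> float:
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        if x[0] == y[0]:
            return 1.0
        return 0.0
    res = stats.ttest_ind(y, x, equal_var=equal_var, alternative=alternative)
    return float(res.pvalue)


def timepoint_tests(
    ctrl: TimePointSeries,
    alc: TimePointSeries,
    one_tailed_zts: Mapping[float, str] | None = None,
    equal_var: bool = True,
) -> dict[float, float]:
    """Student t-test of alcohol vs control at each shared ZT.

    ``one_tailed_zts`` maps a ZT to a pre-registered direction for the
    alcohol group ("greater" or "less"); all other ZTs are two-tailed.
    Returns {zt: p}.
    """
    one_tailed_zts = dict(one_tailed_zts or {})
    shared = sorted(set(np.unique(ctrl.zt)) & set(np.unique(alc.zt)))
    if len(shared) < len(np.unique(ctrl.zt)) or len(shared) < len(np.unique(alc.zt)):
        warnings.warn("ZT grids differ; testing only shared time points", stacklevel=2)
    out = {}
    for z in shared:
        x = ctrl.values[ctrl.zt == z]
        y = alc.values[alc.zt == z]
        if x.size < 2 or y.size < 2:
            raise ValueError(f"need >= 2 replicates per group at ZT{z:g}")
        alternative = one_tailed_zts.get(z, "two-sided")
        out[float(z)] = _ttest(x, y, equal_var, alternative)
    return out


def fold_change_screen(
    table: pd.DataFrame,
    p_values: Mapping[str, float] | None = None,
    treatments: tuple[str, str] = ("control", "alcohol"),
    p_threshold: float = 0.05,
    equal_var: bool = True,
) -> tuple[list[DEGeneRecord], pd.DataFrame]:
    """Fold-change tiering of a single-ZT screen.

    For each analyte: fold change = mean(alcohol)/mean(control); "strong"
    tier at symmetric fold change >= 2 with p < threshold, "moderate" at
    >= 1.5 and < 2.  p-values are taken from ``p_values`` when given,
    else computed as two-tailed Student t-tests.  Returns the records and
    a tier-by-direction count table.
    """
    ctrl_label, alc_label = treatments
    records = []
    for analyte, sub in table.groupby("analyte", sort=True):
        x = sub.loc[sub[TREAT_COL] == ctrl_label, VALUE_COL].to_numpy()
        y = sub.loc[sub[TREAT_COL] == alc_label, VALUE_COL].to_numpy()
        if x.size == 0 or y.size == 0:
            raise ValueError(f"both treatments required for {analyte!r}")
        if x.mean() <= 0 or y.mean() <= 0:
            raise ValueError(f"non-positive group mean for {analyte!r}")
        fc = y.mean() / x.mean()
        if p_values is not None:
            p = float(p_values[analyte])
        else:
            p = _ttest(x, y, equal_var, "two-sided")
        mag = fc if fc >= 1 else 1.0 / fc
        tier = None
        if p < p_threshold:
            if mag >= 2.0:
                tier = "strong"
            elif mag >= 1.5:
                tier = "moderate"
        records.append(DEGeneRecord(str(analyte), float(fc), "up" if fc >= 1 else "down", p, tier))
    counts = pd.DataFrame(
        0,
        index=pd.Index(["strong", "moderate"], name="tier"),
        columns=pd.Index(["up", "down"], name="direction"),
    )
    for rec in records:
        if rec.tier is not None:
            counts.loc[rec.tier, rec.direction] += 1
    return records, counts


def _two_way_fit(df: pd.DataFrame):
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    model = smf.ols(f"{VALUE_COL} ~ C({TIME_COL}) * C({TREAT_COL})", data=df).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = anova_lm(model, typ=2)
    table = table.rename(
        index={
            f"C({TIME_COL})": "Time",
            f"C({TREAT_COL})": "Treatment",
            f"C({TIME_COL}):C({TREAT_COL})": "Interaction",
        }
    )
    return model, table


def twoway_anova_tukey(
    table: pd.DataFrame,
    transform: str = "auto",
    normality_alpha: float = 0.05,
    compute_tukey: bool = True,
) -> AnovaResult:
    """Time x Treatment fixed-effects ANOVA for one analyte's long table.

    With ``transform='auto'``, residual normality is checked
    (Shapiro-Wilk); on rejection a log then a sqrt transform of the
    values is attempted, keeping the first that passes (or the best of
    the three).  Tukey HSD is run across all Time x Treatment cells and
    the control-vs-alcohol contrast within each ZT is reported.
    """
    df = table.copy()
    if df[TIME_COL].nunique() < 2 or df[TREAT_COL].nunique() < 2:
        raise ValueError("two-way ANOVA needs >= 2 levels of both factors (empty cells)")
    cells = df.groupby([TIME_COL, TREAT_COL], sort=True)[VALUE_COL].count()
    expected = df[TIME_COL].nunique() * df[TREAT_COL].nunique()
    if len(cells) < expected or (cells < 2).any():
        thin = cells[cells < 2].index.tolist() if len(cells) == expected else "missing cells"
        raise ValueError(f"need >= 2 replicates in every Time x Treatment cell: {thin}")

    candidates = ["none", "log", "sqrt"] if transform == "auto" else [transform]
    chosen = None
    best = None
    for name in candidates:
        if name == "log":
            if (df[VALUE_COL] <= 0).any():
                continue
            vals = np.log(df[VALUE_COL])
        elif name == "sqrt":
            if (df[VALUE_COL] < 0).any():
                continue
            vals = np.sqrt(df[VALUE_COL])
        else:
            vals = df[VALUE_COL]
        trial = df.assign(**{VALUE_COL: vals})
        model, tab = _two_way_fit(trial)
        sw_p = float(stats.shapiro(model.resid).pvalue) if len(model.resid) <= 5000 else 1.0
        if best is None or sw_p > best[0]:
            best = (sw_p, name, trial, tab)
        if sw_p >= normality_alpha:
            chosen = (sw_p, name, trial, tab)
            break
    if chosen is None:
        chosen = best
    _, name, trial, tab = chosen

    tukey_pairs: dict[float, float] = {}
    if compute_tukey:
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        labels = trial[TIME_COL].astype(str) + "|" + trial[TREAT_COL].astype(str)
        res = pairwise_tukeyhsd(trial[VALUE_COL].to_numpy(), labels.to_numpy())
        frame = pd.DataFrame(res.summary().data[1:], columns=res.summary().data[0])
        for _, row in frame.iterrows():
            z1, t1 = str(row["group1"]).split("|")
            z2, t2 = str(row["group2"]).split("|")
            if z1 == z2 and t1 != t2:
                tukey_pairs[float(z1)] = float(row["p-adj"])

    return AnovaResult(table=tab, tukey_pairs=tukey_pairs, transform_applied=name)


def amplitude_ratio(ctrl: TimePointSeries, alc: TimePointSeries) -> AmplitudeRatio:
    """Peak-to-trough fold change of per-ZT means, and the alcohol/control ratio.

    p2t = max/min of the per-ZT means of each series (>= 1 by
    construction); the ratio is rounded half-up to one decimal, matching
    the reporting convention of published amplitude tables.
    """
    p2ts = []
    for s in (ctrl, alc):
        means = np.array([s.values[s.zt == z].mean() for z in np.unique(s.zt)])
        if np.any(means <= 0):
            raise ValueError("per-ZT means must be positive")
        p2ts.append(float(means.max() / means.min()))
    control_p2t, alcohol_p2t = p2ts
    return AmplitudeRatio(
        analyte=ctrl.analyte,
        control_p2t=control_p2t,
        alcohol_p2t=alcohol_p2t,
        ratio=round_half_up(alcohol_p2t / control_p2t, 1),
    )


def ratio_from_p2t(control_p2t: float, alcohol_p2t: float) -> float:
    """Alcohol/control amplitude ratio from already-computed peak-to-trough values."""
    return round_half_up(alcohol_p2t / control_p2t, 1)


def phase_cluster_summary(
    de_records: Iterable[DEGeneRecord],
    rhythm_calls: Iterable,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Direction x phase-bin contingency and 4-h phase histogram of DE CCGs.

    ``rhythm_calls`` are classified :class:`~zeitgeber.jtk.RhythmCall`
    objects joined on analyte; only calls with is_ccg are counted.
    Returns (contingency with index direction, columns day/night;
    histogram with index direction, columns 4-h windows).
    """
    calls = {c.analyte: c for c in rhythm_calls}
    bins = [f"ZT{z}-{z + 4}" for z in range(0, 24, 4)]
    contingency = pd.DataFrame(
        0, index=pd.Index(["up", "down"], name="direction"), columns=["day", "night"]
    )
    hist = pd.DataFrame(0, index=pd.Index(["up", "down"], name="direction"), columns=bins)
    for rec in de_records:
        call = calls.get(rec.analyte)
        if call is None or not call.is_ccg or call.best_phase is None:
            continue
        contingency.loc[rec.direction, call.phase_bin] += 1
        window = int((call.best_phase % 24.0) // 4) * 4
        hist.loc[rec.direction, f"ZT{window}-{window + 4}"] += 1
    return contingency, hist


def platform_correlation(fc_a: Sequence[float], fc_b: Sequence[float]) -> tuple[float, float]:
    """Pearson correlation between two matched fold-change vectors (e.g. array vs qPCR)."""
    r, p = stats.pearsonr(np.asarray(fc_a, float), np.asarray(fc_b, float))
    return float(r), float(p)
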