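"""End-to-end orchestration of the analysis stages on synthetic inputs.

``run_pipeline`` executes simulate -> cosinor -> bioluminescence ->
circular statistics -> rhythm detection -> differential expression,
writing every intermediate CSV, a run log and a summary report.  The run
is deterministic under the configured seed: per-stage seeds are derived
from a single ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .biolum import extract_features
from .circstats import mww_test, rayleigh_test
from .cosinor import TimePointSeries, fit_table
from .de import amplitude_ratio
from .io import write_phase_samples, write_timecourse, write_trace
from .jtk import jtk_table
from .presets import BIOLUM_PRESETS, PHASE_PRESETS, TIMECOURSE_PRESETS
from .simulate import (
    ExperimentDesign,
    PhaseSampleParams,
    simulate_biolum,
    simulate_phase_sample,
    simulate_timecourse,
)

logger = logging.getLogger("zeitgeber")


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of a demo run (JSON-compatible key/value file)."""

    seed: int = 0
    out_dir: str = "zeitgeber_run"
    analytes: tuple[str, ...] = tuple(sorted(TIMECOURSE_PRESETS))
    zts: tuple[float, ...] = (0.0, 4.0, 8.0, 12.0, 16.0, 20.0)
    n_per_cell: int = 5
    alpha: float = 0.05
    q_threshold: float = 0.1
    period_min: float = 20.0
    period_max: float = 28.0

    def __post_init__(self):
        for name in ("alpha", "q_threshold"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie in (0, 1)")
        if not (0.0 < self.period_min <= self.period_max <= 48.0):
            raise ValueError("period band must lie within (0, 48]")
        unknown = set(self.analytes) - set(TIMECOURSE_PRESETS)
        if unknown:
            raise ValueError(f"unknown analyte presets: {sorted(unknown)}")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "PipelineConfig":
        data = json.loads(Path(path).read_text())
        data.update({k: v for k, v in overrides.items() if v is not None})
        for key in ("analytes", "zts"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


def _configure_logging(out_dir: Path) -> None:
    logger.setLevel(logging.INFO)
    logger.handlers.clear()
    for handler in (logging.StreamHandler(sys.stderr), logging.FileHandler(out_dir / "run.log", mode="w")):
        handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        logger.addHandler(handler)


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        return inner
    return wrap


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every analysis stage; returns the summary report (also written as JSON)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _configure_logging(out)
    logger.info("zeitgeber %s, seed %d", __version__, config.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(config.seed).spawn(8)]
    report: dict = {"seed": config.seed, "version": __version__}

    # --- simulate ------------------------------------------------------
    @_stage("simulate")
    def _simulate():
        design = ExperimentDesign(zts=config.zts, n_per_cell=config.n_per_cell, seed=seeds[0])
        params = {
            (analyte, treatment): TIMECOURSE_PRESETS[analyte][treatment]
            for analyte in config.analytes
            for treatment in design.treatments
        }
        table = simulate_timecourse(design, params)
        write_timecourse(table, out / "timecourse.csv")
        return design, table

    design, table = _simulate()
    logger.info("simulated %d rows for %d analytes", len(table), len(config.analytes))

    # --- cosinor -------------------------------------------------------
    @_stage("cosinor")
    def _cosinor():
        fits = fit_table(table, alpha=config.alpha)
        fits.to_csv(out / "cosinor_fits.csv", index=False)
        return fits

    fits = _cosinor()
    cg_shift = {}
    for analyte in config.analytes:
        sub = fits[fits["analyte"] == analyte].set_index("treatment")
        if bool(sub["rhythmic"].all()):
            delta = (sub.loc["alcohol", "CG"] - sub.loc["control", "CG"]) % 24.0
            cg_shift[analyte] = round(min(delta, 24.0 - delta), 2)
    report["cg_shift_h"] = cg_shift
    report["no_fit"] = sorted(
        f"{r.analyte}/{r.treatment}" for r in fits.itertuples() if not r.rhythmic
    )

    # --- bioluminescence ----------------------------------------------
    @_stage("biolum")
    def _biolum():
        rows = []
        for i, (name, params) in enumerate(sorted(BIOLUM_PRESETS.items())):
            trace = simulate_biolum(params, seed=seeds[1] + i)
            write_trace(trace, out / f"biolum_{name}.csv")
            feats = extract_features(trace)
            rows.append(
                {
                    "trace_id": name,
                    "first_peak_zt": feats.first_peak_zt,
                    "amplitude1": feats.amplitude_cycle1,
                    "amplitude2": feats.amplitude_cycle2,
                    "period": feats.period,
                    "rhythmic": feats.rhythmic,
                    "n_peaks": feats.n_peaks,
                }
            )
        frame = pd.DataFrame(rows)
        frame.to_csv(out / "biolum_features.csv", index=False)
        return frame

    report["biolum"] = _biolum().set_index("trace_id").to_dict("index")

    # --- circular statistics ------------------------------------------
    @_stage("circstats")
    def _circstats():
        samples = {}
        for i, (name, params) in enumerate(sorted(PHASE_PRESETS.items())):
            p = PhaseSampleParams(**{**asdict(params), "seed": seeds[2] + i})
            samples[name] = simulate_phase_sample(p, group=name)
        write_phase_samples(samples.values(), out / "phases.csv")
        rows = []
        for name, sample in samples.items():
            res = rayleigh_test(sample)
            rows.append(
                {"group": name, "test": res.name, "statistic": res.statistic,
                 "p": res.p_value, "mean_phase": res.mean_phase, "r": res.r}
            )
        mww = mww_test(samples["liver_control"], samples["liver_alcohol"], seed=seeds[3])
        rows.append({"group": "control-vs-alcohol", "test": mww.name,
                     "statistic": mww.statistic, "p": mww.p_value,
                     "mean_phase": None, "r": None})
        frame = pd.DataFrame(rows)
        frame.to_csv(out / "circstats.csv", index=False)
        return frame

    circ = _circstats()
    report["phase_map_tests"] = circ.to_dict("records")

    # --- rhythm detection ---------------------------------------------
    @_stage("jtk")
    def _jtk():
        rng = np.random.default_rng(seeds[4])
        times = np.arange(0.0, 48.0, 4.0)
        rows = {}
        for analyte in config.analytes:
            p = TIMECOURSE_PRESETS[analyte]["control"]
            y = p.mean_curve(times % 24.0)
            rows[analyte] = y + rng.normal(0.0, 0.1 * max(p.mesor, 1.0), times.size)
        matrix = pd.DataFrame(rows).T.reset_index()
        matrix.columns = ["analyte"] + [f"CT{int(t)}" for t in times]
        calls = jtk_table(matrix, q_threshold=config.q_threshold,
                          period_min=config.period_min, period_max=config.period_max)
        calls.to_csv(out / "rhythm_calls.csv", index=False)
        return calls

    calls = _jtk()
    report["n_ccg"] = int(calls["is_ccg"].sum())

    # --- differential expression --------------------------------------
    @_stage("de")
    def _de():
        ratios = []
        for analyte in config.analytes:
            ctrl = TimePointSeries.from_timecourse(table, analyte, "control")
            alc = TimePointSeries.from_timecourse(table, analyte, "alcohol")
            ar = amplitude_ratio(ctrl, alc)
            ratios.append(
                {"analyte": analyte, "control_p2t": round(ar.control_p2t, 3),
                 "alcohol_p2t": round(ar.alcohol_p2t, 3), "ratio": ar.ratio}
            )
        frame = pd.DataFrame(ratios)
        frame.to_csv(out / "amplitude_ratios.csv", index=False)
        return frame

    report["amplitude_ratios"] = _de().set_index("analyte")["ratio"].to_dict()

    (out / "report.json").write_text(json.dumps(report, indent=2, default=float))
    logger.info("report written to %s", out / "report.json")
    return report
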