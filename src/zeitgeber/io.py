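"""CSV readers/writers for the pipeline's three table schemas.

* time-course table: ``analyte,treatment,zt,replicate,value``
* bioluminescence trace: ``time_h,counts`` (start ZT supplied separately)
* phase samples: ``group,phase_h``

All times are decimal hours.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .biolum import BiolumTrace
from .circstats import PhaseSample

TIMECOURSE_COLUMNS = ["analyte", "treatment", "zt", "replicate", "value"]


def read_timecourse(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(TIMECOURSE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"time-course CSV missing columns: {sorted(missing)}")
    return df[TIMECOURSE_COLUMNS]


def write_timecourse(table: pd.DataFrame, path: str | Path) -> None:
    table[TIMECOURSE_COLUMNS].to_csv(path, index=False)


def read_trace(path: str | Path, start_zt: float) -> BiolumTrace:
    df = pd.read_csv(path)
    if not {"time_h", "counts"} <= set(df.columns):
        raise ValueError("trace CSV must have columns time_h,counts")
    return BiolumTrace(start_zt=start_zt, times=df["time_h"].to_numpy(), counts=df["counts"].to_numpy())


def write_trace(trace: BiolumTrace, path: str | Path) -> None:
    pd.DataFrame({"time_h": trace.times, "counts": trace.counts}).to_csv(path, index=False)


def read_phase_samples(path: str | Path) -> dict[str, PhaseSample]:
    df = pd.read_csv(path)
    if not {"group", "phase_h"} <= set(df.columns):
        raise ValueError("phase CSV must have columns group,phase_h")
    return {
        str(g): PhaseSample(str(g), sub["phase_h"].to_numpy(dtype=float))
        for g, sub in df.groupby("group", sort=True)
    }


def write_phase_samples(samples, path: str | Path) -> None:
    frames = [
        pd.DataFrame({"group": s.group, "phase_h": np.asarray(s.phases)}) for s in samples
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
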