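"""Illustrative analyte presets for demo runs of the pipeline.

These parameter sets are documentation fixtures, not data: they encode
the qualitative diurnal effects of chronic alcohol feeding reported for
mouse liver (elevated and phase-advanced per2/per3, damped Npas2,
bimodal and phase-delayed Cyp7a1, bimodal triglycerides with an advanced
center of gravity, anti-phase total bile acid and NAD/NADH profiles) so
that an end-to-end run exercises every downstream behaviour: phase
shifts, amplitude changes, bimodality and a flat profile that draws a
"no fit" marker.
"""

from __future__ import annotations

from .biolum import BiolumTrace  # noqa: F401  (re-export convenience)
from .simulate import BiolumParams, PhaseSampleParams, RhythmParams

#: analyte -> treatment -> ground-truth rhythm (illustrative values)
TIMECOURSE_PRESETS: dict[str, dict[str, RhythmParams]] = {
    "per2": {
        "control": RhythmParams(mesor=3.0, harmonics=((1, 1.8, 10.2),), noise_cv=0.2),
        "alcohol": RhythmParams(mesor=4.2, harmonics=((1, 1.1, 6.5),), noise_cv=0.2),
    },
    "per3": {
        "control": RhythmParams(mesor=2.6, harmonics=((1, 2.0, 10.6),), noise_cv=0.2),
        "alcohol": RhythmParams(mesor=3.0, harmonics=((1, 1.2, 5.3),), noise_cv=0.2),
    },
    "npas2": {
        "control": RhythmParams(mesor=10.0, harmonics=((1, 9.0, 2.0),), noise_cv=0.2),
        "alcohol": RhythmParams(mesor=3.0, harmonics=((1, 1.3, 12.0),), noise_cv=0.2),
    },
    "cyp7a1": {
        "control": RhythmParams(mesor=2.0, harmonics=((1, 1.2, 16.0),), noise_cv=0.2),
        "alcohol": RhythmParams(
            mesor=3.0, harmonics=((1, 1.0, 4.0), (2, 0.8, 4.0)), noise_cv=0.2
        ),
    },
    "tg": {
        "control": RhythmParams(mesor=30.0, harmonics=((1, 12.0, 0.0),), noise_cv=0.2),
        "alcohol": RhythmParams(
            mesor=62.0, harmonics=((1, 14.0, 8.0), (2, 8.0, 0.0)), noise_cv=0.2
        ),
    },
    "tba": {
        "control": RhythmParams(mesor=8.0, harmonics=((1, 3.0, 1.0),), noise_cv=0.25),
        "alcohol": RhythmParams(mesor=13.0, harmonics=((1, 5.0, 13.0),), noise_cv=0.25),
    },
    "nad_nadh": {
        "control": RhythmParams(mesor=6.0, harmonics=((1, 2.0, 13.0),), noise_cv=0.15),
        "alcohol": RhythmParams(mesor=2.0, harmonics=((1, 0.8, 1.1),), noise_cv=0.15),
    },
    "flat": {
        "control": RhythmParams(mesor=5.0, noise_cv=0.2),
        "alcohol": RhythmParams(mesor=5.0, noise_cv=0.2),
    },
}

#: liver explant reporter traces: control peaks ~ZT11, alcohol anti-phase ~ZT22.5,
#: with a lower amplitude; both damped with a slow downward drift.  noise_sd
#: reflects photon-counting statistics at these rates (~sqrt(300/s / 600 s)
#: ~ 0.7 counts/s shot noise on a 10-min bin, scaled up for biological
#: irregularity of the explant).
BIOLUM_PRESETS: dict[str, BiolumParams] = {
    "liver_control": BiolumParams(
        start_zt=4.0, peak_zt=11.0, initial_amplitude=120.0,
        damping_rate=0.01, baseline_drift=(300.0, -1.5), noise_sd=2.0,
    ),
    "liver_alcohol": BiolumParams(
        start_zt=4.0, peak_zt=22.5, initial_amplitude=55.0,
        damping_rate=0.015, baseline_drift=(260.0, -1.2), noise_sd=2.0,
    ),
}

#: explant peak-phase samples (sizes as in the liver phase-map comparison)
PHASE_PRESETS: dict[str, PhaseSampleParams] = {
    "liver_control": PhaseSampleParams(n=14, mean_phase=11.0, concentration=8.0),
    "liver_alcohol": PhaseSampleParams(n=17, mean_phase=22.5, concentration=8.0),
}
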