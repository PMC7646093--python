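"""Scheduled PRM inclusion list from a spectral library.

PRM validates a shortlist of candidate biomarkers by targeting their
precursors in a retention-time window around the predicted elution.  The
schedule needs the library's iRT values mapped back to this run's gradient
(the inverse of a calibration fit) and a window of +/- 5 min per precursor.
"""

from dialibkit import (
    BuildConfig,
    CalibrationFit,
    PRMScheduleConfig,
    export_prm_schedule,
    run_build,
)
from dialibkit.simulate import SimulationConfig, simulate_runs

table, spectra, truth = simulate_runs(
    n_runs=3, n_psms=400, seed=33, config=SimulationConfig(rt_noise_sd=5.0)
)
result = run_build(table, spectra, BuildConfig(seed=33))

# pretend this is the PRM run's calibration: iRT = RT/36 - 10
fit = CalibrationFit(slope=1 / 36.0, intercept=-10.0, r_squared=1.0, n_points_used=3)
targets = [e.key.peptide.sequence for e in result.library.targets[:5]] + ["NOTINLIBK"]
schedule, missing, warnings = export_prm_schedule(
    result.library, targets, fit,
    PRMScheduleConfig(rt_halfwidth_minutes=5.0, max_concurrent_precursors=100),
)
print(schedule.to_string(index=False))
print(f"\nevery window is {schedule['End [min]'].iloc[0] - schedule['Start [min]'].iloc[0]:.0f} "
      "min wide (center +/- 5 min)")
print("requested but absent from the library:", missing)
for w in warnings:
    print("warning:", w)
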