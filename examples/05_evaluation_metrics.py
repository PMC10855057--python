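"""Evaluate paired RR estimates and flag fluctuation segments.

MAE, RMSE, mean absolute percentage error, and CP2 (the share of windows
within 2 breaths/min) summarise agreement with the reference; the
fluctuation flagger marks windows whose variability betrays motion or
light artifacts so they can be excluded transparently.
"""
import numpy as np

from respyre import (WaveformSignal, evaluate_estimates,
                     flag_fluctuation_segments, segment_windows)

reference = np.array([12.0, 15.0, 18.0, 14.0, 20.0])
estimated = np.array([12.5, 14.0, 18.0, np.nan, 23.0])  # NaN = abstained

report = evaluate_estimates(reference, estimated)
print(f"MAE  {report.mae:.3f} breaths/min")
print(f"RMSE {report.rmse:.3f} breaths/min")
print(f"MAPE {report.mean_abs_percentage_error:.2f} %")
print(f"CP2  {report.cp2:.1f} % of windows within 2 breaths/min")
print(f"windows evaluated: {report.n_windows}, abstained: {report.n_invalid}")

# fluctuation flagging: 10 windows, one corrupted by a large step
fs = 4.0
t = np.arange(int(10 * 60 * fs)) / fs
x = np.sin(2 * np.pi * 0.25 * t)
x[int(3 * 60 * fs) + 40: int(3 * 60 * fs) + 200] += 10.0
ws = segment_windows(WaveformSignal(x, fs), int(60 * fs))
ws.subject_ids = ["demo"] * ws.n_windows
for subject, interval, reason in flag_fluctuation_segments(ws):
    print(f"flagged window {interval}: {reason}")
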