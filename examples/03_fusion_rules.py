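"""Fusion of the per-modulation RR estimates.

Smart fusion averages the BW/AM/FM estimates only when they agree (SD
under 4 breaths/min) and abstains otherwise; the temporal median then
smooths consecutive windows of the same subject.
"""
from respyre import RrEstimate, smart_fusion, temporal_fusion


def est(value, valid=True):
    return RrEstimate(value=value if valid else None, window=(0.0, 60.0),
                      method="spectral", valid=valid)


agreeing = smart_fusion([est(10.0), est(11.0), est(12.0)])
print(f"{{10, 11, 12}} -> value {agreeing.value} (SD 1 < 4: fused to the mean)")

conflicting = smart_fusion([est(5.0), est(15.0), est(25.0)])
print(f"{{5, 15, 25}}  -> valid={conflicting.valid} (SD 10 >= 4: abstains)")

history = [est(15.0), est(None, valid=False), est(17.0)]
smoothed = temporal_fusion(history)
print(f"history [15, abstained, 17] -> temporal median {smoothed.value}")
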