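"""Process an aortic-root flow waveform: statistics, normalization, group average.

Builds synthetic one-cycle waveforms for two subjects from their published
(T, Qmean, Qpeak) triples, derives the clinical statistics, and averages the
normalized waveforms the way cohort figures are assembled.
"""

import aortahemo as ah

subjects = ah.make_subject_table().set_index("subject")

waveforms = {}
for name in ("H1", "TS2"):
    row = subjects.loc[name]
    w = ah.make_waveform(ah.WaveformTemplate(T=row.T_s, Qmean=row.Qmean_ml_s, Qpeak=row.Qpeak_ml_s))
    waveforms[name] = w
    s = ah.waveform_stats(w, D_mm=row.D_mm)
    print(f"{name}: Qmean {s.Qmean:6.1f} ml/s  Qpeak {s.Qpeak:6.1f} ml/s  "
          f"HR {s.HR:5.1f} bpm  CO {s.CO:4.2f} l/min")
    print(f"     peak systole t1={s.t_peak:.3f} s, max deceleration t2={s.t_maxdecel:.3f} s "
          f"({s.peak_decel:6.2f} m/s^2), mid-diastole t3={s.t_middiastole:.3f} s")

# Normalize by mean flow and period, then average across the two subjects:
normalized = [ah.normalize_waveform(w) for w in waveforms.values()]
avg = ah.group_average(normalized)
print(f"\ngroup-averaged normalized waveform: mean {avg.cycle_mean():.4f} "
      f"(unit by construction), peak {avg.flow.max():.2f} x mean flow")
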