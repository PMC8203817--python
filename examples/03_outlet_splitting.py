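"""Split aortic flow among the arch branches and descending aorta by Murray's law.

With no per-outlet flow measurements, each outlet receives a share of the
inlet flow proportional to its diameter squared (the large-vessel exponent).
"""

import aortahemo as ah

outlets = ah.OutletSet(
    (("RSA", 8.0), ("RCCA", 7.5), ("LCCA", 7.0), ("LSA", 8.5), ("DescAo", 16.0)),
    exponent=2.0,
)
split = ah.murray_split(outlets)
print("outlet flow percentages (n = 2):")
for name, pct in split.as_percentages(1).items():
    print(f"  {name:7}: {pct:5.1f} %")
print(f"  sum    : {sum(split.fractions.values()) * 100:.1f} %   (conservation)")

# Apply the split to a pulsatile inlet waveform: each outlet gets the scaled cycle
w = ah.make_waveform(ah.WaveformTemplate(T=0.57, Qmean=90.0, Qpeak=294.0))
per_outlet = ah.apply_split(split, w)
desc = per_outlet["DescAo"]
print(f"\ndescending-aorta waveform peak: {desc.flow_ml_s.max():.0f} ml/s "
      f"of the {w.flow_ml_s.max():.0f} ml/s inlet peak")
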