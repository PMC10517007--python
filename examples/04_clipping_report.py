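"""Quantify recorder overload at 99% and 90% of the signal peak.

Close-range vocalizations exceed the recorder's dynamic range; the report
counts samples at or above a fraction of the recording's peak amplitude.
"""

import trawlpam as tp
from trawlpam import study
from trawlpam.clipping import ClippingReport

# On synthetic audio: drive a noise scene into the rails deliberately
rec = tp.make_noise(10.0, 48000, rms=0.1, seed=4)
clipped, spans = tp.inject_clipping(rec, 2.5)
for report in tp.overload_percentages(clipped):
    print(f"threshold {report.threshold_fraction:.2f} x peak: "
          f"{report.clipped_count} of {report.total_count} samples "
          f"({report.clipped_percent:.2f}%)")
print(f"{len(spans)} clipped spans injected by the simulator")

# The published recording's own overload arithmetic: counts over
# duration x rate, reproducing the reported percentages
total = study.total_samples()
for frac, count in [(0.99, study.OVERLOAD_COUNT_99), (0.90, study.OVERLOAD_COUNT_90)]:
    r = ClippingReport(frac, 1.0, count, total)
    print(f"study recording, {frac:.0%} threshold: {r.clipped_percent:.2f}% "
          f"of {total:,} samples")
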