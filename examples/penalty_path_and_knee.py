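"""Choose the changepoint penalty automatically from the data.

CROPS enumerates every optimal segmentation over a penalty range; the
count-vs-penalty curve has a knee separating over- from under-fitting,
located by a two-line segmented fit. The knee is the recommended
penalty for that series.
"""

import numpy as np

import vistrack as vt

rng = np.random.default_rng(3)
series = np.repeat([1.8, 0.2, 1.4], [70, 60, 70]) + rng.normal(0, 0.3, 200)

lo, hi = vt.default_beta_range(series)
path = vt.crops_path(series, lo, hi)
print("penalty intervals (beta_low, beta_high -> #changepoints):")
for b0, b1, seg in path.intervals[:6]:
    print(f"  [{b0:9.4f}, {b1:9.4f}) -> m = {seg.m}")
print(f"  ... {len(path.intervals)} intervals in total")

knee = vt.fit_knee(path)
print(f"knee penalty psi = {knee.psi:.3f} (converged: {knee.converged})")
seg = vt.pelt_segment(series, knee.psi)
print(f"segmentation at the knee: changepoints = {list(seg.changepoints)}")
# The knee sits where adding penalty stops removing many changepoints:
# below it the series is over-segmented by noise, above it genuine
# transitions start to be missed.
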