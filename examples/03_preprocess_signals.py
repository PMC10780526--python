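"""Turn a raw signal tensor into a normalized network input.

Shows the exact shape chain 16x16x5000 -> 256x5000 -> 256x250 -> 256x256
and the per-row min-max normalization: every antenna pair's trace is mapped
onto [0, 1] so weak far-pair signals carry as much contrast as strong
near-pair ones.
"""

import numpy as np

from mwtomo.fdtd import SignalTensor
from mwtomo.pipeline import downsample, minmax_normalize, pad_columns, preprocess, stack_signals

rng = np.random.default_rng(0)
# stand-in tensor with per-pair amplitudes spanning 4 orders of magnitude
scales = 10.0 ** rng.uniform(-4, 0, size=(16, 16, 1))
tensor = SignalTensor(data=scales * rng.normal(size=(16, 16, 5000)))

stacked = stack_signals(tensor)
decimated = downsample(stacked, 20)
padded = pad_columns(decimated, 6)
result = minmax_normalize(padded)
print("shapes:", tensor.data.shape, "->", stacked.shape, "->",
      decimated.shape, "->", padded.shape, "->", result.values.shape)

one_shot = preprocess(tensor)
print("one-call chain identical:", bool(np.array_equal(one_shot.values, result.values)))
print("row minima all 0:", bool(np.allclose(result.values.min(axis=1), 0)))
print("row maxima all 1:", bool(np.allclose(result.values.max(axis=1), 1)))
print("row 17 encodes pair (tx, rx) =", result.channel_pair(17))
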