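"""Strip-pooling attention on a feature map with an elongated structure.

Row/column mean pooling turns a (C, H, W) map into one descriptor per row
and per column; the attention module mixes them through 1-D convolutions,
fuses the two directions, and emits a sigmoid gate multiplied back onto the
input.  On a map containing a horizontal bar, the row holding the bar gets
a distinct gate profile.
"""

import numpy as np

from stripfuse import StripAttention, strip_pool_horizontal, strip_pool_vertical
from stripfuse.autodiff import Tensor

rng = np.random.default_rng(0)
z = 0.05 * rng.random((1, 2, 8, 8)).astype(np.float32)
z[0, :, 3, 1:7] = 1.0  # a horizontal bar in row 3

rows = strip_pool_horizontal(z)
cols = strip_pool_vertical(z)
print("row means (channel 0):", np.round(rows[0, 0], 2))
print("col means (channel 0):", np.round(cols[0, 0], 2))
# the bar dominates its row mean but is diluted across eight column means

att = StripAttention(2, rng=np.random.default_rng(1)).eval()
gate = att.gate(Tensor(z)).data
out = att(Tensor(z)).data
print(f"gate range: ({gate.min():.3f}, {gate.max():.3f})  -- strictly inside (0,1)")
print(f"bar-row gate mean {gate[0, :, 3].mean():.3f} vs "
      f"other rows {np.delete(gate[0], 3, axis=1).mean():.3f}")
print("output energy / input energy:",
      round(float((out**2).sum() / (z**2).sum()), 3))
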