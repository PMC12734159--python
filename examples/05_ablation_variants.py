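"""Build the six ablation variants and compare their structure.

A: spatial blocks only; B: A + shallow strip head; C: residual blocks only;
D: C + deep strip head; E: full backbone with plain heads; F: the complete
model with both strip-pooling combination heads.  ``ablation_suite`` trains
any subset over seeds; here we just inspect the architectures, which is
instant.
"""

import numpy as np

from stripfuse import VARIANTS, build_variant

print(f"{'variant':<8s} {'parameters':>12s} {'strip heads':>12s}")
for name in VARIANTS:
    net = build_variant(name, seed=0)
    print(f"{name:<8s} {net.num_parameters():>12,d} {net.combo_head_count():>12d}")

full = build_variant("F", seed=0)
print("\nfull model, per-module parameter counts:")
print(full.summary())

x = np.random.default_rng(0).random((1, 1, 224, 224), dtype=np.float32)
probs = full.eval().forward(x)
print("\nforward pass on one 224x224 image -> class probabilities:",
      np.round(probs[0], 3), " (sum", round(float(probs.sum()), 6), ")")
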