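"""Forward-simulate the human CBF+BOLD study and summarize its transients.

Builds the 3 T static/flickering checkerboard design (55 s blocks, TR
2.2 s), runs the generative model with the reference parameter set, and
prints shape metrics of the noise-free CBF and BOLD responses in percent
signal change.
"""

from pdcm import (
    integrate,
    make_design,
    reference_parameters,
    transient_metrics,
)
from pdcm.observe import assemble_prediction

spec = make_design("I")
params = reference_parameters("I")
dataset = assemble_prediction(spec, integrate(params, spec), params)

print("Experiment I (static vs flickering checkerboard, CBF + BOLD, 3 T)")
for block in dataset.blocks:
    m = transient_metrics(block.values, block.times, spec.condition(block.condition))
    under = f"{m.undershoot:7.2f}% at +{m.undershoot_time:.0f}s" if m.undershoot else "   none"
    print(
        f"  {block.modality:4s}/{block.condition:8s}: "
        f"peak {m.peak:6.2f}% at {m.time_to_peak:5.1f}s | "
        f"end/peak {m.end_peak_ratio:4.2f} | undershoot {under}"
    )

print(
    "\nThe static condition adapts during stimulation (end/peak well below 1)\n"
    "and its CBF recovers without an undershoot, while the flickering\n"
    "condition holds a CBF plateau and undershoots after stimulus offset.\n"
    "BOLD end/peak ratios are smaller than CBF ones: venous-volume\n"
    "uncoupling (tau ~ 69 s) sharpens the BOLD transients."
)
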