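"""Generate a synthetic OCT phantom and segment its ILM surface.

Builds a small volume with an attached epiretinal-membrane band, runs the
vertical active contour on one slice, and reports how close the recovered
surface is to the known geometry.
"""

import numpy as np

from ermmap import PhantomSpec, generate_phantom, segment_ilm

spec = PhantomSpec(
    n_slices=8,
    speckle_sigma=0.08,
    erm_regions=[(2, 7, 30, 95, 0)],  # slices 2-6, columns 30-94, attached
    rng_seed=7,
)
phantom = generate_phantom(spec)
volume = phantom.volume("example")

print(f"volume: {volume.n_slices} slices of {volume.height}x{volume.width} px")
print(f"true ILM depth range: rows {phantom.true_ilm.min():.1f}"
      f" to {phantom.true_ilm.max():.1f}")
for s, label in [(0, "membrane-free"), (3, "with ERM band")]:
    contour = segment_ilm(volume.scan(s))
    mae = float(np.mean(np.abs(contour.rows - phantom.true_ilm[s])))
    print(f"snake mean absolute error on slice {s} ({label}): {mae:.2f} px")
# On the membrane-free slice the error is well under 1 px: the snake locks
# onto the vitreous-retina edge despite the speckle. On the ERM slice the
# first bright edge from above is the membrane itself, so the contour rides
# a few pixels above the anatomical surface there — which is exactly where
# the feature window should be centered for ERM detection.
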