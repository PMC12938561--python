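"""Compare multi-planar fusion strategies for the whole-tumor mask.

The stage-1 mask is thresholded independently in the axial, coronal and
sagittal planes; the fusion rule decides how many planes must agree. The
strict AND keeps only voxels detected in all three, trading a little
sensitivity for far fewer false positives — the Dice scores below show
the nesting AND >= MAJORITY >= OR on a clean phantom.
"""

from glioseg import (FusionStrategy, PhantomSpec, PipelineConfig, dice,
                     generate_phantom, run_stage1)
from glioseg.volume_io import BinaryMask

spec = PhantomSpec(seed=0)
volume, ground_truth = generate_phantom(spec)
wt = BinaryMask(ground_truth.data > 0, spacing=spec.spacing)

for strategy in FusionStrategy:
    mask = run_stage1(volume, PipelineConfig(fusion=strategy))
    print(f"{strategy.value:13s} dice={dice(mask, wt):.3f} voxels={mask.count()}")
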