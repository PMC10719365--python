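"""Render a synthetic DAPI field and segment the nuclei in it.

Builds one multi-channel z-stack with two planted PBMC nuclei, runs the
2-D candidate -> cleared crop -> 3-D Chan-Vese pipeline, and prints the
per-nucleus QC verdicts next to the generative ground truth.
"""

import numpy as np

from chromascope import SyntheticSpec, generate_nucleus_image, segment_stack

spec = SyntheticSpec(shape_zyx=(17, 170, 170))
stack, truths = generate_nucleus_image(spec, seed=7, n_nuclei=2)
print(f"field: {stack.voxels.shape[0]} channels, {stack.shape_zyx} (z, y, x) voxels")
print(f"planted nuclei: {len(truths)}")

for rec in segment_stack(stack):
    status = "PASS" if rec.qc_pass else f"REJECT ({rec.reject_reason})"
    vol = rec.mask3d.sum() * rec.spec.voxel_volume_um3
    height = rec.mask3d.any(axis=(1, 2)).sum() * rec.spec.dz_um
    print(f"  {rec.nucleus_id}: {status}  volume={vol:.1f} um^3  height={height:.1f} um")

for t in truths:
    print(f"  truth {t.nucleus_id}: volume={t.volume_um3:.1f} um^3")

# The recovered volumes should sit within a few percent of the rendered
# truth; QC enforces the 400-voxel (1.62 um^3) floor and 2.5-10 um height
# window, so every PASS row is a usable single nucleus.
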