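"""Undoing burial distortion: rule 1 (shear) and rule 2 (compaction).

A synthetic vertebra with a perfectly circular centrum is compacted
dorso-ventrally and sheared, as burial under kilometres of sediment does to
real fossils. Rule 1 restores the perpendicular anatomical axis triad;
rule 2 stretches dorso-ventrally until the centrum section is round again.
"""

import numpy as np

from paleobody import AxisTriad, decompress_round, measure_roundness, restore_orthogonality
from paleobody.synthetic_specimen import distort, make_vertebra, random_distortion

vert = make_vertebra()
shear, compression = random_distortion(seed=2015)
damaged = distort(vert.mesh, shear=shear, dv_compression=compression)
print(f"applied compaction factor: {compression:.3f} (dorso-ventral), plus random shear")

# rule 1: the triad fitted to the distorted bone is the image of the true axes
fitted = AxisTriad((0, 0, 0), *damaged.transform.linear.T)
recovered, t1 = restore_orthogonality(damaged.mesh, fitted, AxisTriad.orthonormal())
rms = np.sqrt(np.mean(np.sum((recovered.vertices - vert.mesh.vertices) ** 2, axis=1)))
print(f"rule 1 recovery RMS vs the undistorted original: {rms:.2e} cm")

# rule 2 alone on a purely compacted copy: the section forces the scale
squashed = distort(vert.mesh, dv_compression=0.6).mesh
sec = measure_roundness(squashed, (0, 0, 0), (1, 0, 0), (0, 1, 0))
fixed, t2, scale = decompress_round(squashed, sec, (0, 0, 1))
after = measure_roundness(fixed, (0, 0, 0), (1, 0, 0), (0, 1, 0))
print(f"rule 2: measured roundness {sec.ratio:.3f} -> stretch {scale:.4f} -> roundness {after.ratio:.6f}")
print()
print(
    "With homogeneous deformation both rules are exact affine inverses: the\n"
    "recovery RMS is at machine precision and the rule-2 stretch equals the\n"
    "reciprocal of the applied compaction (1/0.6 = 1.6667)."
)
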