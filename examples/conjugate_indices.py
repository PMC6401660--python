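"""Measure every conjugate index on one simulated cell–bead conjugate.

Renders a noisy 3-D phantom with known ground truth, segments it with the
automated rule (actin → cell, DAPI → nucleus, tubulin → centrosome), and
prints the recovered indices next to the generator truth.
"""

import numpy as np

import synquant as sq

truth = sq.SceneTruth.with_polarity(
    0.45,
    perpendicular_offset=0.5,
    seed=21,
    lysosome_polarization_true=0.7,
    channels=sq.default_channels(snr=10),
)
stack = sq.generate_conjugate(truth)
seg = sq.ConjugateSegmentation.from_stack(stack, truth.bead_center, truth.bead_radius)
report = sq.measure_conjugate(stack, seg)

true_dist = np.linalg.norm(np.array(truth.centrosome_pos) - np.array(truth.nucleus_center))
print(f"polarity index        {report.polarity_index:+.3f}   (truth {truth.polarity_true:+.3f})")
print(f"centrosome-nucleus    {report.centrosome_nucleus_distance:.2f} um (truth {true_dist:.2f} um)")
print(f"actin density index   {report.density_index['actin']:.3f}   (>1 = centrosomal accumulation)")
print(f"LAMP-1 recruitment    {report.recruitment_pct['lamp1']:.1f} %  (lysosome delivery to the bead)")

# A polarity of +1 would put the centrosome at the bead mass center; 0 at the
# cell center. The density index compares fluorescence density in a 1 um
# region at the centrosome with the whole-cell density.
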