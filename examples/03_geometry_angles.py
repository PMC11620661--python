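"""Recover planted representational geometry with RDM / MDS angles.

Simulates 12 participants per planted angle, builds 4-condition RDMs
from pairwise decoding, embeds them with classical MDS, and prints the
jackknife (leave-one-participant-out group-averaged RDM) target-target
angle next to the per-participant average. The jackknife estimate sits
closer to the planted angle at theta = 0 because averaging RDMs before
embedding cancels the noise that otherwise biases angles upward.
"""

import vwmgeom as vg

quartets = vg.enumerate_quartets("exp1", "exp1-cross-distractor")[:2]
print("planted   participant-mean   jackknife-group")
for theta in (0.0, 30.0, 60.0, 90.0):
    datasets = [
        vg.generate_dataset(
            vg.GeometryParams(theta_deg=theta, seed=200 + 13 * p + int(theta)),
            "exp1").data
        for p in range(12)
    ]
    rdms = vg.participant_rdms(datasets, quartets)
    part = vg.participant_angles(rdms, quartets)
    jack = vg.jackknife_group_angles(rdms, quartets)
    print(f"  {theta:4.0f}         {part.target_target.mean():6.1f}"
          f"            {jack.target_target.mean():6.1f}")
print("\nangles in degrees, folded to [0, 90]. Jackknife endpoints track"
      "\nthe planted geometry; intermediate angles are compressed by the"
      "\naccuracy-based distance measure (see docs/methods.md).")
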