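"""Score a perturbed model against its reference with LDDT and all-atom LDDT.

Builds a synthetic 60-residue protein, perturbs residues 20-35 with 2 A
Gaussian noise, and prints per-segment and model-level scores in both modes.
"""

import numpy as np

from plddtkit import (
    LDDTConfig, SyntheticSpec, compute_lddt, make_backbone, make_decoy,
)

reference = make_backbone(60, seed=1)
decoy, _ = make_decoy(reference, SyntheticSpec(
    length=60, seed=2, error_segments=((20, 35, 2.0),)))

for mode in ("calpha", "all_atom"):
    prof = compute_lddt(reference, decoy, LDDTConfig(mode=mode))
    noisy = np.mean([prof.per_residue[i] for i in range(20, 36)])
    clean = np.mean([prof.per_residue[i] for i in range(1, 16)])
    print(f"{mode:>8s}: model-level {prof.model_level:5.1f}  "
          f"perturbed segment {noisy:5.1f}  untouched segment {clean:5.1f}")

# The perturbed segment scores far below the untouched one; the all-atom
# variant is typically the more stringent of the two because side-chain
# atoms see errors the CA trace hides.  Scores are on the 0-100 LDDT scale.
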