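"""Per-residue fluctuation across a model ensemble and its link to quality.

Generates a protein with one badly modeled segment, emulates five dropout
replicates whose jitter tracks the local error, and shows that RMSF
anticorrelates with true LDDT.
"""

import numpy as np
from scipy.stats import spearmanr

from plddtkit import SyntheticSpec, compute_rmsf, make_protein

rec = make_protein(SyntheticSpec(
    length=60, seed=5, error_segments=((25, 40, 3.0),)))

rmsf = compute_rmsf(rec.ensemble).per_residue
lddt = rec.true_lddt.per_residue
shared = sorted(set(rmsf) & set(lddt))
rho = spearmanr([rmsf[i] for i in shared], [lddt[i] for i in shared]).statistic

inside = np.mean([rmsf[i] for i in range(25, 41)])
outside = np.mean([rmsf[i] for i in shared if not 25 <= i <= 40])
print(f"RMSF inside bad segment : {inside:.2f} A")
print(f"RMSF outside            : {outside:.2f} A")
print(f"Spearman(RMSF, true LDDT): {rho:.2f}")

# Poorly modeled residues fluctuate more across replicates, so the rank
# correlation with true LDDT is strongly negative — this is why RMSF is a
# useful input feature for confidence prediction.
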