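"""Classify tripeptide backbone conformations into rotamer codes.

Builds an ideal capped FFF tripeptide at extended-beta targets, measures
its six backbone dihedrals, classifies it, and enumerates the full state
space of the clustering scheme.
"""

import numpy as np

from trifil import (BuildSpec, RegionMap, backbone_dihedrals, build_tripeptide,
                    classify_peptide, enumerate_codes)

regions = RegionMap.default()

# one residue per (phi, psi) pair; (-120, 130) is the extended-beta basin
frame = build_tripeptide(BuildSpec("FFF", ((-120.0, 130.0),) * 3))
dihedrals = backbone_dihedrals(frame, peptide_id=0)
code = classify_peptide(frame, 0, regions)

print("backbone dihedrals (phi1 psi1 phi2 psi2 phi3 psi3):",
      np.round(dihedrals, 1))
print("conformation code:", code)
# 'b-b-b' is the cross-beta strand conformation that dominates many
# tripeptide fibril cores

n_default = len(enumerate_codes(regions))
n_unreduced = len(enumerate_codes(RegionMap.default(reduce_terminal=False)))
print(f"distinct codes: {n_default} (default scheme), "
      f"{n_unreduced} without the terminal beta/PPII merge")
# 48 uniquely defined conformations; 4^3 = 64 when every basin is kept
# distinct at the C-terminal residue
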