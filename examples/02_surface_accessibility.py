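"""Per-residue solvent accessibility and the surface definition.

A residue is 'surface' when its accessible area on the isolated chain
exceeds 50% of the same residue type's accessibility in an extended
Ala-X-Ala tripeptide.
"""

from mutexbind.structures import accessibility_table, surface_residues
from mutexbind.synthetic import FixtureSpec, make_toy_chain

chain = make_toy_chain(FixtureSpec(seed=4, n_residues=10, scaffold="helix"))
print(accessibility_table(chain), end="")

surf = surface_residues(chain)
print(f"\n{len(surf.members)}/{len(chain)} residues are surface-exposed "
      "(rel_acc > 0.5)")
# asa is the Shrake-Rupley accessible area in A^2; rel_acc divides it by
# the extended-tripeptide reference, so 1.0 means 'as exposed as in a
# fully extended peptide'. Thin toy helices are almost entirely surface.
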