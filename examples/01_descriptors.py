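"""Compute 2D descriptors for a tiagabine-like inhibitor.

Builds one R-nipecotic-acid analog (diaryl oxime head, 5-atom linker) and
prints the count/polarity descriptors and the scaffold indicators.
"""

from rdkit import Chem

from binqsar.descriptors import descriptor_vector

smiles = "C(c1ccccc1C)(c1ccccc1)=NOCCCN1CCC[C@@H](C(O)=O)C1"
mol = Chem.MolFromSmiles(smiles)
vec = descriptor_vector(mol)

print(f"compound: {smiles}")
for name in ("a_count", "b_count", "b_rotN", "opr_brigid", "wienerPol",
             "vdw_area", "PEOE_VSA_FPPOS",
             "ind_R_nipecotic", "ind_S_nipecotic", "ind_guvacine"):
    print(f"  {name:16s} {vec[name]:10.4f}")

# a_count/b_count include implicit hydrogens; wienerPol counts heavy-atom
# pairs at graph distance 3 (a compactness/branching measure); vdw_area is
# the approximate van der Waals surface in A^2; the indicator triple shows
# the molecule carries the R-nipecotic-acid head group.
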