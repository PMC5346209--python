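"""Tanimoto similarity between two compounds, with fold-length sensitivity.

Usage:  python examples/similarity_pair.py SMILES1 SMILES2

Prints the Morgan (radius 2) Tanimoto at several fold lengths and, when
Open Babel is installed, the FP2 value.  Folding a fingerprint into
fewer bits can only create collisions, so the similarity typically
drifts upward as the bit space shrinks — worth checking whenever a
printed two-decimal Tc is compared across software.
"""

import sys

from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

from mostsim import compute_fingerprint, fp2_available, tanimoto
from mostsim.fingerprints import Fingerprint

if len(sys.argv) != 3:
    sys.exit(__doc__)
smiles_a, smiles_b = sys.argv[1], sys.argv[2]

print(f"A: {smiles_a}\nB: {smiles_b}\n")
for n_bits in (1024, 2048, 4096):
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=n_bits)
    fps = []
    for smi in (smiles_a, smiles_b):
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            sys.exit(f"error: unparseable SMILES {smi!r}")
        fps.append(Fingerprint("morgan", frozenset(gen.GetFingerprint(mol).GetOnBits()), n_bits))
    print(f"Morgan radius 2, {n_bits:>5} bits: Tc = {tanimoto(*fps):.2f}")

if fp2_available():
    fps = [compute_fingerprint(s, scheme="fp2") for s in (smiles_a, smiles_b)]
    print(f"FP2 (Open Babel), 1024 bits: Tc = {tanimoto(*fps):.2f}")
else:
    print("FP2 unavailable (obabel not on PATH)")
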