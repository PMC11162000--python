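"""Tokenize a SMILES string and a protein sequence.

SMILES become atom-level tokens (bracket atoms and Cl/Br kept whole,
ring/bond/branch symbols as their own tokens); proteins become
consecutive non-overlapping amino-acid 3-mers. These tokens are the
"words" of the embedding corpus.
"""

from sgcpi.tokenizer import canonicalize_smiles, tokenize_protein, tokenize_smiles

smiles = "OC(=O)c1ccccc1Cl"  # 2-chlorobenzoic acid
canon = canonicalize_smiles(smiles)
print("input SMILES:     ", smiles)
print("canonical SMILES: ", canon)
print("tokens:           ", list(tokenize_smiles(canon).tokens))
print("atoms only:       ", list(tokenize_smiles(canon, atoms_only=True).tokens))

seq = "MKVLAGHETWYNNPQRSC"
print("\nprotein:", seq)
print("3-mers: ", list(tokenize_protein(seq).tokens))
# 18 residues -> exactly 6 non-overlapping 3-mer words; a 19th residue
# would be dropped, since windows start at 0 with stride 3.
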