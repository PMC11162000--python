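"""Label an activity table by IC50 and apply the redundancy filters.

Pairs with IC50 < 100 nM are positive, > 10000 nM negative, anything in
between (or missing) excluded. Compounds more than 80% Tanimoto-similar
(Morgan fingerprints) to an already-kept compound are dropped by the
greedy redundancy pass, as are >80%-identical proteins.
"""

import pandas as pd

from sgcpi.curation import (
    drop_invalid,
    label_records,
    morgan_bits,
    redundancy_filter,
    sequence_identity,
    tanimoto,
)

table = pd.DataFrame(
    {
        "compound_id": ["c1", "c2", "c3", "c4"],
        "smiles": ["CCO", "O=[Si]=O", "CCN", "CCS"],
        "protein_id": ["p1", "p1", "p2", "p2"],
        "sequence": ["MKVLAGHET"] * 4,
        "ic50_nM": [12.0, 40.0, None, 50000.0],
    }
)
kept, report = drop_invalid(table)
labeled = label_records(kept)
print("dropped:", report, " (silica is carbon-free -> inorganic proxy)")
print(labeled[["compound_id", "ic50_nM", "label"]].to_string(index=False))

smis = ["CCO", "OCC", "c1ccccc1"]  # OCC is ethanol again
fps = {s: morgan_bits(s) for s in smis}
kept_smis = redundancy_filter(smis, lambda a, b: tanimoto(fps[a], fps[b]))
print("\nafter Tanimoto>0.8 greedy filter:", kept_smis)
print("identity ACDEF vs ACDEY:", sequence_identity("ACDEF", "ACDEY"))
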