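"""Train skip-gram (negative sampling) vectors on a small compound corpus.

Builds a corpus from synthetic compounds, trains a 32-dimensional SGNS
model, and shows that the per-epoch mean objective rises (the model is
learning to tell true contexts from sampled negatives) and how an entity
embedding is the mean of its token vectors.
"""

import numpy as np

from sgcpi.embedding import SkipgramConfig, build_vocab, embed_entity, train_skipgram
from sgcpi.synthetic import generate_compounds
from sgcpi.tokenizer import tokenize_smiles

compounds = generate_compounds(40, seed=1)
corpus = [tokenize_smiles(c.smiles_canonical, entity_id=c.id) for c in compounds]
vocab = build_vocab(corpus, min_count=1)
print(f"corpus: {len(corpus)} molecules, vocabulary of {len(vocab)} tokens")

table, epoch_objs = train_skipgram(corpus, vocab, SkipgramConfig(d=32, epochs=5, seed=0))
print("per-epoch mean objective:", np.round(epoch_objs, 4))
# less negative = higher likelihood of observed (center, context) pairs

emb = embed_entity(corpus[0], table)
print(f"\nentity {emb.entity_id}: {emb.vector.shape[0]}-d vector, "
      f"OOV fraction {emb.oov_fraction:.2f}")
print("first 5 components:", np.round(emb.vector[:5], 4))
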