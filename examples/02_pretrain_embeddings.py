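"""Pretrain CBOW word embeddings on an unlabeled report corpus.

Trains 64-dimensional vectors on ~1,000 synthetic reports and shows that
lexical variants of one anatomical concept ("d-colon", "dc", "desc", ...)
end up closer to each other than random word pairs -- the property that
lets a tagger generalize across report shorthand.
"""

import itertools

import numpy as np

from coloner import GeneratorConfig, generate_corpus, train_cbow
from coloner.preprocess import sentences_of

_, unlabeled = generate_corpus(GeneratorConfig(n_documents=50, n_unlabeled=1000, seed=0))
sentences = [[t.lower() for t in s.tokens] for text in unlabeled
             for s in sentences_of(text)]
print(f"training CBOW on {len(sentences)} sentences ...")
emb = train_cbow(sentences, dimension=64, window=5, min_count=3, epochs=5, seed=0)
print(f"vocabulary: {len(emb.vocab)} words; matrix {emb.matrix.shape}")

variants = [v for v in ("d-colon", "dc", "desc", "descending") if v in emb.vocab]
pairs = list(itertools.combinations(variants, 2))
variant_cos = [emb.cosine(a, b) for a, b in pairs]
rng = np.random.default_rng(1)
words = emb.vocab.words[2:]
random_cos = [emb.cosine(words[i], words[j])
              for i, j in rng.integers(0, len(words), (500, 2)) if i != j]

for (a, b), c in zip(pairs, variant_cos):
    print(f"  cosine({a!r}, {b!r}) = {c:.3f}")
print(f"mean variant cosine   : {np.mean(variant_cos):.3f}")
print(f"median random cosine  : {np.median(random_cos):.3f}")
print("Variants of 'descending colon' are measurably more similar than "
      "arbitrary word pairs.")
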