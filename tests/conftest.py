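"""Shared fixtures; pins BLAS to one thread for bit-reproducible runs."""

import os

# must precede the first numpy import anywhere in the test session
os.environ.setdefault("OPENBLAS_NUM_THREADS", "1")
os.environ.setdefault("OMP_NUM_THREADS", "1")
os.environ.setdefault("MKL_NUM_THREADS", "1")

import numpy as np
import pytest

from coloner.schema import LabelSet, TagVocabulary
from coloner.synthgen import GeneratorConfig, generate_corpus


@pytest.fixture(scope="session")
def tag_vocab() -> TagVocabulary:
    return TagVocabulary()


@pytest.fixture(scope="session")
def label_set() -> LabelSet:
    return LabelSet.default()


@pytest.fixture(scope="session")
def tiny_corpus():
    """20 annotated documents, typo-free, for fast unit tests."""
    docs, unlabeled = generate_corpus(
        GeneratorConfig(n_documents=20, n_unlabeled=30, seed=42, typo_rate=0.0))
    return docs, unlabeled


@pytest.fixture(scope="session")
def small_corpus():
    """500 documents with default noise, for distributional checks."""
    docs, unlabeled = generate_corpus(
        GeneratorConfig(n_documents=500, n_unlabeled=500, seed=7))
    return docs


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
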