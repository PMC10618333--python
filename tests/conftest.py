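"""Shared fixtures: vocabularies, synthetic corpora, and the (expensive)
pretrained toy generator reused by the deeper end-to-end checks."""

from __future__ import annotations

import numpy as np
import pytest

from hitgen.fixtures import FixtureSpec, make_affinity_table, make_corpus
from hitgen.tokenizer import TokenVocabulary


@pytest.fixture(scope="session")
def vocab() -> TokenVocabulary:
    return TokenVocabulary()


@pytest.fixture(scope="session")
def small_corpus() -> list[str]:
    """300 scaffold-decorated drug-like molecules."""
    return make_corpus(FixtureSpec(n=300, seed=7))


@pytest.fixture(scope="session")
def corpus_2000() -> list[str]:
    return make_corpus(FixtureSpec(n=2000, seed=2))


@pytest.fixture(scope="session")
def affinity_table():
    """The full-scale synthetic affinity table (1,453 molecules, noise 0.3)."""
    return make_affinity_table(FixtureSpec(n=1453, seed=4, noise_sd=0.3))


@pytest.fixture(scope="session")
def pretrained_generator(corpus_2000):
    """Toy-scale pretrained SMILES language model (shared: expensive)."""
    from hitgen.workflows import pretrain_generator

    gen, trace = pretrain_generator(corpus_2000, seed=1)
    gen._pretrain_trace = trace
    return gen


@pytest.fixture(scope="session")
def toy_predictor(affinity_table):
    """Configuration-I predictor trained on the synthetic affinity table."""
    from hitgen.workflows import train_toy_predictor

    model, report = train_toy_predictor(affinity_table, seed=0)
    model._report = report
    return model


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
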