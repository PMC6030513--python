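"""Shared fixtures.

The reference synthetic corpus (2000 citations, 10% RCT prevalence, seed
1, PT tags simulated at 93.7% sensitivity / 97.6% specificity) and the
pipelines fitted on it are session-scoped: CNN training dominates the
suite's runtime, so every test that needs a fitted pipeline shares these.
"""

from __future__ import annotations

import numpy as np
import pytest

from rctscreen.corpus import Citation, Label, TokenizedDoc
from rctscreen.model import RCTScreeningModel, ScreeningConfig
from rctscreen.synthetic import GeneratorParams, generate_corpus, simulate_pt_tags

CORPUS_SEED = 1
PT_SENSITIVITY = 0.937
PT_SPECIFICITY = 0.976
FIT_SEEDS = (0, 1, 2)


def make_doc(tokens: list[str], n_title: int = 0) -> TokenizedDoc:
    flags = [i < n_title for i in range(len(tokens))]
    return TokenizedDoc(tokens=list(tokens), in_title=flags)


def make_citation(title: str, abstract: str = "", **kw) -> Citation:
    return Citation(record_id=kw.pop("record_id", "c1"), title=title, abstract=abstract, **kw)


@pytest.fixture(scope="session")
def ref_corpus():
    params = GeneratorParams(n_docs=2000, prevalence=0.1, seed=CORPUS_SEED)
    corpus = generate_corpus(params)
    simulate_pt_tags(corpus, PT_SENSITIVITY, PT_SPECIFICITY, CORPUS_SEED + 1)
    return corpus


@pytest.fixture(scope="session")
def ref_labels(ref_corpus):
    return np.array([1 if c.label is Label.RCT else 0 for c in ref_corpus])


@pytest.fixture(scope="session")
def ref_results(ref_corpus):
    """Fast-configuration pipeline fitted with training seed 0."""
    return RCTScreeningModel(ref_corpus, ScreeningConfig.fast(seed=FIT_SEEDS[0])).fit()


@pytest.fixture(scope="session")
def multi_seed_results(ref_corpus, ref_results):
    """Pipelines fitted with three training seeds on the same corpus."""
    results = [ref_results]
    for seed in FIT_SEEDS[1:]:
        results.append(
            RCTScreeningModel(ref_corpus, ScreeningConfig.fast(seed=seed)).fit()
        )
    return results
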