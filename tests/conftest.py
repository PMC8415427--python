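import numpy as np
import pytest

import tissuehet as th


@pytest.fixture(scope="session")
def small_sim():
    """A compact seeded corpus with mixtures and mislabels plus planted signatures."""
    cfg = th.SimConfig(
        n_tissues=5,
        genes_total=1500,
        signature_genes_per_tissue=50,
        samples_per_tissue=24,
        contamination_fraction=0.15,
        mislabel_fraction=0.05,
        rng_seed=11,
    )
    expr, ann, truth = th.simulate_corpus(cfg)
    queries, refs = th.planted_signatures(truth)
    vocab = th.default_vocabulary(cfg.tissues)
    ann = th.apply_vocabulary(ann, vocab)
    return {
        "config": cfg,
        "expr": expr,
        "annotations": ann,
        "truth": truth,
        "queries": queries,
        "refs": refs,
        "vocab": vocab,
    }


@pytest.fixture(scope="session")
def small_enrichment(small_sim):
    table = th.run_enrichment(small_sim["expr"], small_sim["queries"] + small_sim["refs"])
    return table


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
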