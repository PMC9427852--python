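import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def annotation():
    """Five genes, mixed biotypes, varying lengths."""
    return pd.DataFrame(
        {
            "gene_name": ["alpha", "beta", "gamma", "delta", "eps"],
            "biotype": ["protein_coding", "lincRNA", "protein_coding",
                        "protein_coding", "pseudogene"],
            "effective_length": [1000, 2000, 100, 500, 300],
        },
        index=pd.Index(["g1", "g2", "g3", "g4", "g5"], name="gene_id"),
    )


@pytest.fixture
def uniform_annotation():
    """Length-1000 protein-coding annotation for n genes, built on demand."""
    def make(gene_ids):
        return pd.DataFrame(
            {
                "gene_name": list(gene_ids),
                "biotype": "protein_coding",
                "effective_length": 1000,
            },
            index=pd.Index(gene_ids, name="gene_id"),
        )
    return make


def random_pwm(length, seed, floor=1e-4):
    """Random Dirichlet PWM (shared helper for motif tests)."""
    from tntseq.motifs import PositionWeightMatrix
    rng = np.random.default_rng(seed)
    p = rng.dirichlet(np.ones(4) * 0.5, size=length)
    p = np.maximum(p, floor)
    p /= p.sum(axis=1, keepdims=True)
    return PositionWeightMatrix(f"RAND_L{length}_S{seed}", f"RBP{seed}", p)
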