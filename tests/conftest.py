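import numpy as np
import pandas as pd
import pytest

from atacrna.io import GeneModel, GenomicInterval, PWM


@pytest.fixture
def toy_genes() -> list[GeneModel]:
    return [
        GeneModel("GC1", "C1", "chr1", "+", 10000, 15000, "protein_coding",
                  exons=[(10000, 11000), (14000, 15000)]),
        GeneModel("GC2", "C2", "chr1", "-", 40000, 52000, "protein_coding",
                  exons=[(40000, 41000), (51000, 52000)]),
        GeneModel("GL1", "L1", "chr1", "+", 70000, 72000, "antisense",
                  target_gene_id="GC2"),
        GeneModel("GL2", "L2", "chr2", "+", 10000, 13000, "lincRNA"),
    ]


@pytest.fixture
def consensus_pwm() -> PWM:
    # near-deterministic 12-mer, the length scale of curated TF matrices
    probs = np.full((12, 4), 0.1 / 3)
    cons = [0, 1, 2, 3, 0, 2, 1, 3, 2, 0, 1, 3]
    for i, b in enumerate(cons):
        probs[i, b] = 0.9
    return PWM("M1", "TF_X", probs / probs.sum(axis=1, keepdims=True))


def consensus_of(pwm: PWM) -> str:
    return "".join("ACGT"[int(b)] for b in pwm.probs.argmax(axis=1))


@pytest.fixture
def de_table_toy() -> pd.DataFrame:
    """A hand-built differential-expression table: 100 DEGs of one
    comparison, 20 of them lncRNAs, with 6 lncRNAs in the top 10 by |FC|."""
    rng = np.random.default_rng(5)
    n = 100
    gene_ids = [f"g{i:03d}" for i in range(n)]
    # ranks 0..9 = top 10; place lncRNAs at 6 of the top-10 ranks
    biotype = np.array(["protein_coding"] * n, dtype=object)
    lnc_ranks = [0, 2, 3, 5, 7, 8] + list(range(40, 54))
    biotype[lnc_ranks] = "lincRNA"
    log2fc = np.linspace(8, 2.1, n)  # strictly decreasing |FC|
    return pd.DataFrame(
        {
            "gene_id": gene_ids,
            "comparison": "D0vsD14",
            "base_mean": 100.0,
            "log2fc": log2fc,
            "p": rng.uniform(0, 0.001, n),
            "q": np.linspace(1e-6, 0.04, n),
            "is_deg": True,
            "biotype": biotype,
        }
    )
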