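import numpy as np
import pandas as pd
import pytest

from npcpgx import diffexpr, simulate


@pytest.fixture(scope="session")
def small_expression():
    """Normalized 500-gene x 20-sample cohort with a 40-gene signature."""
    counts, meta, truth = simulate.gen_expression(
        n_genes=500, n_samples=20, group_log2fc=3.0, dispersion=(0.02, 0.1),
        seed=11, n_signature=40,
    )
    _, norm = diffexpr.normalize_counts(diffexpr.drop_all_zero_genes(counts))
    return norm, meta, truth


@pytest.fixture(scope="session")
def toy_callsets():
    """Three caller call tables over a shared 4-variant toy universe.

    Keys: A seen by caller1 only, B by caller1+2, C by all three, D by
    caller2 only, E by caller3 only.
    """

    def row(name, caller, t_depth):
        return {
            "chrom": "chr1", "pos": {"A": 10, "B": 20, "C": 30, "D": 40, "E": 50}[name],
            "ref": "C", "alt": "T", "caller": caller,
            "t_depth": t_depth, "t_alt": 10, "n_alt": 0, "pop_af": 0.0,
            "vaf": 10 / t_depth, "sample": "T1", "gene": f"GENE_{name}",
            "consequence": "missense",
        }

    c1 = pd.DataFrame([row("A", "c1", 50), row("B", "c1", 60), row("C", "c1", 70)])
    c2 = pd.DataFrame([row("B", "c2", 90), row("C", "c2", 40), row("D", "c2", 55)])
    c3 = pd.DataFrame([row("C", "c3", 80), row("E", "c3", 45)])
    return {"c1": c1, "c2": c2, "c3": c3}


@pytest.fixture
def rng():
    return np.random.default_rng(0)
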