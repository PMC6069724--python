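import numpy as np
import pandas as pd
import pytest

from epinet.genotypes import GenotypeTable, _variant_stats


@pytest.fixture
def make_table():
    """Factory building a GenotypeTable straight from a dosage matrix."""

    def _make(dosage, chrom=None, pos=None, ids=None):
        dosage = np.asarray(dosage, dtype=float)
        n, m = dosage.shape
        if chrom is None:
            chrom = ["1"] * m
        if pos is None:
            pos = [(k + 1) * 100 for k in range(m)]
        if ids is None:
            ids = [f"rs{k}" for k in range(m)]
        stats = [_variant_stats(dosage[:, k]) for k in range(m)]
        variants = pd.DataFrame(
            {
                "id": ids,
                "chrom": [str(c) for c in chrom],
                "pos": pos,
                "allele_minor": ["A"] * m,
                "allele_major": ["G"] * m,
                "maf": [s[0] for s in stats],
                "call_rate": [s[1] for s in stats],
            }
        )
        return GenotypeTable(variants, [f"s{i}" for i in range(n)], dosage)

    return _make


@pytest.fixture
def hwe_dosages():
    """Random Hardy-Weinberg dosage columns for quick constructions."""

    def _draw(n, m, maf=0.3, seed=0):
        rng = np.random.default_rng(seed)
        if np.isscalar(maf):
            maf = np.full(m, maf)
        return np.column_stack(
            [rng.binomial(2, p, size=n).astype(float) for p in maf]
        )

    return _draw
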