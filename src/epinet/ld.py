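"""Linkage-disequilibrium block collapsing.

Consecutive variants in high observed LD produce near-duplicate interaction
models, so runs of them are collapsed to a single representative before the
pair scan.  LD is measured as the squared Pearson correlation of genotype
dosages (composite r-squared — phase is unknown in ped/tped data), and
blocks grow greedily along the genome: a variant joins the current block as
long as the mean r-squared over all pairs in the candidate block stays above
the threshold.  Blocks never span chromosomes.  The block member with the
highest average r-squared to the rest of its block is kept as the
representative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import GenotypeTable

__all__ = ["LDBlock", "pairwise_r2", "build_blocks", "select_representatives", "ld_collapse"]


@dataclass
class LDBlock:
    """A contiguous run of variants (indices into one GenotypeTable)."""

    variant_indices: list[int]
    chrom: str
    mean_r2: float
    representative: int

    @property
    def size(self) -> int:
        return len(self.variant_indices)


def pairwise_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors.

    Computed over pairwise-complete samples.  Returns ``NaN`` (which block
    logic treats as 0) when fewer than 3 complete pairs remain or either
    vector is constant on the shared support.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        return np.nan
    xv, yv = x[ok], y[ok]
    xc = xv - xv.mean()
    yc = yv - yv.mean()
    sxx, syy = xc @ xc, yc @ yc
    if sxx == 0 or syy == 0:
        return np.nan
    r = (xc @ yc) / np.sqrt(sxx * syy)
    return float(min(r * r, 1.0))


def _block_r2_matrix(g: GenotypeTable, idx: list[int]) -> np.ndarray:
    k = len(idx)
    r2 = np.eye(k)
    for a in range(k):
        for b in range(a + 1, k):
            val = pairwise_r2(g.dosage[:, idx[a]], g.dosage[:, idx[b]])
            r2[a, b] = r2[b, a] = 0.0 if np.isnan(val) else val
    return r2


def build_blocks(g: GenotypeTable, r2_threshold: float) -> list[LDBlock]:
    """Partition genome-sorted variants into greedy contiguous LD blocks.

    Sliding left to right within each chromosome: the next variant is
    appended while the mean r-squared over all pairs in the candidate block
    stays >= ``r2_threshold``; otherwise the block is closed and a new one
    starts at the rejected variant.  Singleton blocks have mean r-squared 1
    by convention.
    """
    if not 0.0 < r2_threshold <= 1.0:
        raise ValueError(f"r2_threshold must be in (0, 1], got {r2_threshold}")

    chroms = g.variants["chrom"].astype(str).to_numpy()
    blocks: list[LDBlock] = []
    start = 0
    while start < g.n_variants:
        members = [start]
        pair_sum = 0.0  # sum of r2 over all pairs among members
        r2_to_members: dict[int, float] = {start: 0.0}  # sum of r2 to co-members
        nxt = start + 1
        while nxt < g.n_variants and chroms[nxt] == chroms[start]:
            new_r2 = []
            for m in members:
                val = pairwise_r2(g.dosage[:, m], g.dosage[:, nxt])
                new_r2.append(0.0 if np.isnan(val) else val)
            k = len(members) + 1
            cand_sum = pair_sum + sum(new_r2)
            if cand_sum / (k * (k - 1) / 2) >= r2_threshold:
                for m, val in zip(members, new_r2):
                    r2_to_members[m] += val
                r2_to_members[nxt] = sum(new_r2)
                members.append(nxt)
                pair_sum = cand_sum
                nxt += 1
            else:
                break
        k = len(members)
        if k == 1:
            blocks.append(LDBlock([start], chroms[start], 1.0, start))
        else:
            mean_r2 = pair_sum / (k * (k - 1) / 2)
            # representative: highest average r2 to co-members, tie -> lowest index
            rep = max(members, key=lambda m: (r2_to_members[m] / (k - 1), -m))
            blocks.append(LDBlock(members, chroms[start], mean_r2, rep))
        start = nxt
    return blocks


def select_representatives(
    blocks: list[LDBlock], g: GenotypeTable
) -> tuple[GenotypeTable, pd.DataFrame]:
    """Reduce a GenotypeTable to one representative variant per block.

    Returns the reduced table (genome order preserved) and a block report
    (block id, chromosome, span, members, representative, mean r-squared).
    """
    covered = sorted(i for b in blocks for i in b.variant_indices)
    if covered != list(range(g.n_variants)):
        raise ValueError("blocks do not partition the variant set")

    rows = []
    reps = []
    ids = g.variants["id"]
    pos = g.variants["pos"]
    for k, b in enumerate(blocks):
        reps.append(b.representative)
        rows.append(
            {
                "block": k,
                "chrom": b.chrom,
                "start_bp": int(pos.iloc[b.variant_indices[0]]),
                "end_bp": int(pos.iloc[b.variant_indices[-1]]),
                "n_variants": b.size,
                "members": ",".join(ids.iloc[i] for i in b.variant_indices),
                "representative": ids.iloc[b.representative],
                "mean_r2": b.mean_r2,
            }
        )
    reps = sorted(reps)
    return g.take_variants(reps), pd.DataFrame(rows)


def ld_collapse(g: GenotypeTable, r2_threshold: float) -> tuple[GenotypeTable, pd.DataFrame]:
    """Convenience: build blocks then select representatives."""
    blocks = build_blocks(g, r2_threshold)
    return select_representatives(blocks, g)
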