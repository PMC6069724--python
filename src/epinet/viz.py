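"""Genome-wide interaction visualizations.

Three summaries of a pair scan, each returned as a numeric table with the
figure drawn on top of it:

* a pseudo-Manhattan plot — per variant, the sum of -log10 interaction
  p-values over every pair the variant appears in;
* a chromosome-pair heatmap — the 90th percentile of -log10(p) over all
  pairs linking two chromosomes, min-max normalized to [-1, 1];
* a region-pair map — the same 90th-percentile statistic on windows of a
  user-chosen size along two chromosomes.
"""

from __future__ import annotations

import warnings

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .epistasis import EpistasisTable
from .genotypes import _natural_chrom_key

__all__ = ["pseudo_manhattan", "chrom_interaction_map", "pairwise_chr_map"]

_Q = 90  # percentile of -log10(p) summarizing a group of pairs


def _scores(tbl: EpistasisTable) -> pd.DataFrame:
    ok = tbl.ok_pairs
    return ok[np.isfinite(ok["neglog_p3"])]


def pseudo_manhattan(tbl: EpistasisTable, ax=None) -> tuple[pd.DataFrame, plt.Figure]:
    """Per-variant summed interaction significance along the genome.

    Every variant's score is the sum of -log10(p3) over all tested pairs it
    belongs to (0 if it appears in none); the plot lays variants out by
    cumulative genomic position with alternating chromosome colors.
    """
    if len(tbl) == 0:
        raise ValueError("empty interaction table")
    pairs = _scores(tbl)
    summed = pd.Series(0.0, index=tbl.variants["id"])
    for side in ("snp_i", "snp_j"):
        contrib = pairs.groupby(side)["neglog_p3"].sum()
        summed = summed.add(contrib, fill_value=0.0)
    summed = summed.loc[tbl.variants["id"]]

    table = tbl.variants[["id", "chrom", "pos"]].copy()
    table["summed_score"] = summed.to_numpy()

    chroms = sorted(table["chrom"].astype(str).unique(), key=_natural_chrom_key)
    offset, offsets = 0, {}
    for c in chroms:
        offsets[c] = offset
        offset += int(table.loc[table["chrom"].astype(str) == c, "pos"].max()) + 1
    table["cum_pos"] = [
        offsets[str(c)] + p for c, p in zip(table["chrom"], table["pos"])
    ]

    if ax is None:
        fig, ax = plt.subplots(figsize=(9, 3.5))
    else:
        fig = ax.figure
    for k, c in enumerate(chroms):
        sub = table[table["chrom"].astype(str) == c]
        ax.scatter(sub["cum_pos"], sub["summed_score"], s=8,
                   color=("tab:blue", "tab:orange")[k % 2], label=c)
    ax.set_xlabel("genomic position")
    ax.set_ylabel("sum of -log10(p) over pairs")
    ax.set_title("Per-variant interaction summary")
    return table.drop(columns="cum_pos"), fig


def chrom_interaction_map(tbl: EpistasisTable, ax=None) -> tuple[pd.DataFrame, plt.Figure]:
    """Chromosome-pair interaction strength, normalized to [-1, 1].

    Each (A, B) cell — including the within-chromosome diagonal — is the
    90th percentile of -log10(p3) over all pairs with one variant on A and
    one on B; cells are then mapped linearly so the weakest observed cell is
    -1 and the strongest +1.  Cells with no tested pair stay missing.
    """
    pairs = _scores(tbl)
    if pairs.empty:
        raise ValueError("no usable pairs in the interaction table")
    chroms = sorted(tbl.variants["chrom"].astype(str).unique(), key=_natural_chrom_key)
    if len(chroms) < 2:
        warnings.warn("only one chromosome present; map is a single cell")

    key = pairs.apply(
        lambda r: tuple(sorted((str(r["chr_i"]), str(r["chr_j"])), key=_natural_chrom_key)),
        axis=1,
    )
    q90 = pairs.groupby(key)["neglog_p3"].quantile(_Q / 100.0)

    mat = pd.DataFrame(np.nan, index=chroms, columns=chroms)
    for (a, b), v in q90.items():
        mat.loc[a, b] = v
        mat.loc[b, a] = v

    vals = mat.to_numpy()
    finite = vals[np.isfinite(vals)]
    lo, hi = finite.min(), finite.max()
    if hi == lo:
        warnings.warn("all chromosome-pair scores equal; normalized map set to 0")
        norm = pd.DataFrame(np.where(np.isfinite(vals), 0.0, np.nan),
                            index=chroms, columns=chroms)
    else:
        norm = (mat - lo) / (hi - lo) * 2.0 - 1.0

    if ax is None:
        fig, ax = plt.subplots(figsize=(5, 4.2))
    else:
        fig = ax.figure
    im = ax.imshow(norm.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(chroms)), chroms)
    ax.set_yticks(range(len(chroms)), chroms)
    ax.set_title("Chromosome-pair interaction strength")
    fig.colorbar(im, ax=ax, label="normalized 90th-pct -log10(p)")

    long = norm.stack().rename("normalized").reset_index()
    long.columns = ["chrom_a", "chrom_b", "normalized"]
    long["q90"] = [mat.loc[a, b] for a, b in zip(long["chrom_a"], long["chrom_b"])]
    return long, fig


def pairwise_chr_map(
    tbl: EpistasisTable, chrom_a: str, chrom_b: str, window_bp: int, ax=None
) -> tuple[pd.DataFrame, plt.Figure]:
    """Region x region interaction strength between two chromosomes.

    Each chromosome is binned into consecutive windows of ``window_bp``;
    a cell holds the 90th percentile of -log10(p3) over pairs whose variants
    fall in the two windows (missing when no pair was tested there).
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    chrom_a, chrom_b = str(chrom_a), str(chrom_b)
    variants = tbl.variants
    present = set(variants["chrom"].astype(str))
    for c in (chrom_a, chrom_b):
        if c not in present:
            raise ValueError(f"chromosome {c!r} not present in the table")

    pairs = _scores(tbl)
    sel_ab = (pairs["chr_i"].astype(str) == chrom_a) & (pairs["chr_j"].astype(str) == chrom_b)
    sel_ba = (pairs["chr_i"].astype(str) == chrom_b) & (pairs["chr_j"].astype(str) == chrom_a)
    sub = pd.concat(
        [
            pairs.loc[sel_ab, ["pos_i", "pos_j", "neglog_p3"]].rename(
                columns={"pos_i": "pos_a", "pos_j": "pos_b"}),
            pairs.loc[sel_ba, ["pos_j", "pos_i", "neglog_p3"]].rename(
                columns={"pos_j": "pos_a", "pos_i": "pos_b"}),
        ],
        ignore_index=True,
    )

    def _axis(chrom):
        length = int(variants.loc[variants["chrom"].astype(str) == chrom, "pos"].max())
        return max(1, int(np.ceil(length / window_bp)))

    na, nb = _axis(chrom_a), _axis(chrom_b)
    grid = np.full((na, nb), np.nan)
    if not sub.empty:
        wa = np.minimum((sub["pos_a"].to_numpy() - 1) // window_bp, na - 1).astype(int)
        wb = np.minimum((sub["pos_b"].to_numpy() - 1) // window_bp, nb - 1).astype(int)
        dfg = pd.DataFrame({"wa": wa, "wb": wb, "s": sub["neglog_p3"].to_numpy()})
        for (a, b), grp in dfg.groupby(["wa", "wb"]):
            grid[a, b] = np.percentile(grp["s"], _Q)

    if ax is None:
        fig, ax = plt.subplots(figsize=(5, 4.2))
    else:
        fig = ax.figure
    im = ax.imshow(grid.T, origin="lower", aspect="auto", cmap="viridis",
                   extent=(0, na * window_bp, 0, nb * window_bp))
    ax.set_xlabel(f"chromosome {chrom_a} (bp)")
    ax.set_ylabel(f"chromosome {chrom_b} (bp)")
    ax.set_title("Region-pair interaction strength")
    fig.colorbar(im, ax=ax, label="90th-pct -log10(p)")

    rows = [
        {"window_a": a, "window_b": b, "start_a": a * window_bp,
         "start_b": b * window_bp, "q90": grid[a, b]}
        for a in range(na) for b in range(nb)
    ]
    return pd.DataFrame(rows), fig
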