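"""Weighted interaction network, topological overlap and module detection.

Interaction coefficients are turned into a correlation-like similarity by
rescaling positive and negative b3 values separately onto (0, 1] and
[-1, 0) — so coefficients near zero map to similarity near zero — and the
resulting matrix feeds the topological overlap measure (TOM).  Modules of
mutually interacting variants are obtained by average-linkage clustering of
the TOM dissimilarity and cutting the dendrogram, and each module is then
summarized (first principal component of its standardized member dosages,
the "eigen-SNP") and correlated with the phenotype.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .epistasis import EpistasisTable
from .genotypes import GenotypeTable

__all__ = [
    "SimilarityMatrix",
    "ModuleAssignment",
    "rescale_beta",
    "adjacency_from_similarity",
    "tom",
    "detect_modules",
    "module_trait_correlation",
]


@dataclass
class SimilarityMatrix:
    """Symmetric variant x variant similarity in [-1, 1] with unit diagonal."""

    values: np.ndarray
    variant_ids: list[str]

    def __post_init__(self):
        m = len(self.variant_ids)
        if self.values.shape != (m, m):
            raise ValueError("similarity matrix shape does not match variant ids")


@dataclass
class ModuleAssignment:
    """Variant -> module labels (0 = unassigned) with per-module statistics."""

    labels: pd.Series  # index: variant id, values: int module labels
    linkage: np.ndarray | None = None
    module_stats: pd.DataFrame | None = None
    warnings_: list[str] = field(default_factory=list)

    @property
    def n_modules(self) -> int:
        return int((np.unique(self.labels) > 0).sum())

    def members(self, label: int) -> list[str]:
        return list(self.labels.index[self.labels == label])


def rescale_beta(tbl: EpistasisTable) -> SimilarityMatrix:
    """Map interaction coefficients onto [-1, 1], signs treated separately.

    Positive b3 values are divided by the largest positive b3, negative ones
    by the magnitude of the most negative, so the extremes land exactly on
    +1/-1 while coefficients near zero stay near zero.  Degenerate/unstable
    pairs and pairs absent from the table contribute similarity 0; the
    diagonal is 1.
    """
    ok = tbl.ok_pairs
    if len(tbl) == 0:
        raise ValueError("empty interaction table")
    ids = list(tbl.variants["id"])
    index = {v: k for k, v in enumerate(ids)}
    m = len(ids)

    beta = ok["beta3"].to_numpy(float)
    pos_max = beta[beta > 0].max() if (beta > 0).any() else 0.0
    neg_min = beta[beta < 0].min() if (beta < 0).any() else 0.0
    if pos_max == 0.0 and neg_min == 0.0:
        raise ValueError("no interaction signal: all usable beta3 are zero")

    s = np.zeros((m, m))
    ii = ok["snp_i"].map(index).to_numpy()
    jj = ok["snp_j"].map(index).to_numpy()
    scaled = np.zeros_like(beta)
    scaled[beta > 0] = beta[beta > 0] / pos_max
    scaled[beta < 0] = beta[beta < 0] / abs(neg_min)
    s[ii, jj] = scaled
    s[jj, ii] = scaled
    np.fill_diagonal(s, 1.0)
    return SimilarityMatrix(values=s, variant_ids=ids)


def adjacency_from_similarity(
    s: SimilarityMatrix, power: float = 1.0, signed_mode: str = "unsigned"
) -> np.ndarray:
    """Turn similarity into a non-negative adjacency for the TOM step.

    ``unsigned``: a = |s|^power (the default, with power 1, passes the
    similarity magnitudes straight through); ``signed``: a = ((1+s)/2)^power.
    The diagonal is zeroed, as TOM expects no self-edges.
    """
    if power <= 0:
        raise ValueError(f"power must be positive, got {power}")
    if signed_mode == "unsigned":
        a = np.abs(s.values) ** power
    elif signed_mode == "signed":
        a = ((1.0 + s.values) / 2.0) ** power
    else:
        raise ValueError(f"signed_mode must be 'unsigned' or 'signed', got {signed_mode!r}")
    np.fill_diagonal(a, 0.0)
    return a


def tom(a: np.ndarray) -> np.ndarray:
    """Unsigned topological overlap of a non-negative adjacency matrix.

    tom_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij) with
    k_i = sum_u a_iu; the diagonal is set to 1 and isolated pairs (zero
    denominator) get 0 by convention.
    """
    a = np.asarray(a, dtype=float)
    if a.shape[0] != a.shape[1] or not np.allclose(a, a.T):
        raise ValueError("adjacency must be square and symmetric")
    if a.min() < 0 or a.max() > 1:
        raise ValueError("adjacency entries must lie in [0, 1]")
    if np.any(np.diag(a) != 0):
        a = a.copy()
        np.fill_diagonal(a, 0.0)

    L = a @ a
    k = a.sum(axis=0)
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (L + a) / denom
    t[denom == 0] = 0.0
    np.fill_diagonal(t, 1.0)
    return np.clip(t, 0.0, 1.0)


def _modularity(w: np.ndarray, labels: np.ndarray) -> float:
    """Newman weighted modularity of a partition on similarity graph ``w``."""
    k = w.sum(axis=0)
    W2 = k.sum()  # = 2 * total edge weight
    if W2 == 0:
        return -np.inf
    q = 0.0
    for c in np.unique(labels):
        idx = labels == c
        q += w[np.ix_(idx, idx)].sum() / W2 - (k[idx].sum() / W2) ** 2
    return q


# minimum modularity gain for accepting a branch split during the
# recursive cut; guards against shattering homogeneous modules on noise
_MIN_SPLIT_GAIN = 0.02

# a member must keep at least this fraction of its module's mean
# intra-module connectivity, or it is stripped to grey (and a grey variant
# reaching it against some module is rescued into that module)
_CONNECTIVITY_FRAC = 0.7


def _refine_membership(
    w: np.ndarray, labels: np.ndarray, min_size: int,
    frac: float = _CONNECTIVITY_FRAC, max_rounds: int = 5,
) -> np.ndarray:
    """Connectivity-based membership cleanup after a tree cut.

    Members whose mean within-module TOM falls below ``frac`` of the module
    average are stripped to grey (label 0); grey variants at least that
    connected to some module are pulled in.  Repeats until stable.
    """
    labels = labels.copy()
    for _ in range(max_rounds):
        changed = False
        # strip weakly attached members
        for c in np.unique(labels):
            if c == 0:
                continue
            idx = np.flatnonzero(labels == c)
            if idx.size < max(3, min_size):
                continue
            sub = w[np.ix_(idx, idx)]
            kin = sub.sum(axis=1) / (idx.size - 1)
            cutoff = frac * kin.mean()
            weak = kin < cutoff
            if weak.any() and (~weak).sum() >= 2:
                labels[idx[weak]] = 0
                changed = True
        # rescue grey variants that are strongly connected to a module
        grey = np.flatnonzero(labels == 0)
        mods = [c for c in np.unique(labels) if c != 0]
        for i in grey:
            best_c, best_k = 0, 0.0
            for c in mods:
                idx = np.flatnonzero(labels == c)
                if idx.size < 2:
                    continue
                k_to = w[i, idx].mean()
                sub = w[np.ix_(idx, idx)]
                kin_mean = sub.sum() / (idx.size * (idx.size - 1))
                if k_to >= frac * kin_mean and k_to > best_k:
                    best_c, best_k = c, k_to
            if best_c:
                labels[i] = best_c
                changed = True
        if not changed:
            break
    return labels


def _best_height_cut(w: np.ndarray, Z: np.ndarray) -> tuple[np.ndarray, float]:
    """Best modularity-scoring height cut of one dendrogram (labels, Q)."""
    heights = np.unique(Z[:, 2])
    candidates = np.concatenate(
        [[heights[0] / 2], (heights[:-1] + heights[1:]) / 2]
    )
    n = w.shape[0]
    best_q, best = 0.0, np.ones(n, dtype=int)
    for h in candidates:
        lab = fcluster(Z, t=h, criterion="distance")
        if len(np.unique(lab)) < 2:
            continue
        q = _modularity(w, lab)
        if q > best_q + 1e-12:
            best_q, best = q, lab
    return best, best_q


def _adaptive_cut(w: np.ndarray, Z: np.ndarray, min_size: int) -> np.ndarray:
    """Recursive modularity-guided branch decomposition.

    The dendrogram is cut at the height maximizing weighted modularity on
    the TOM graph; each resulting cluster large enough to split further is
    re-clustered on its own subgraph, and the split is kept only when it
    yields a meaningful modularity gain there.  This isolates tight branches
    nested inside looser ones, which no single global height can separate.
    """
    labels, q = _best_height_cut(w, Z)
    if q <= _MIN_SPLIT_GAIN:
        return np.ones(w.shape[0], dtype=int)
    out = np.zeros(w.shape[0], dtype=int)
    nxt = 1
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        if idx.size >= 2 * min_size:
            sub_w = w[np.ix_(idx, idx)]
            sub_d = 1.0 - sub_w
            np.fill_diagonal(sub_d, 0.0)
            sub_Z = linkage(squareform(sub_d, checks=False), method="average")
            sub_labels = _adaptive_cut(sub_w, sub_Z, min_size)
            sub_sizes = np.bincount(sub_labels)
            # a split must produce at least two clusters of module size,
            # otherwise it only shatters the branch into prunable shards
            if (sub_sizes >= min_size).sum() >= 2:
                for sc in np.unique(sub_labels):
                    out[idx[sub_labels == sc]] = nxt
                    nxt += 1
                continue
        out[idx] = nxt
        nxt += 1
    return out


def detect_modules(
    t: np.ndarray,
    variant_ids: list[str] | None = None,
    min_module_size: int = 10,
    cut_height: float | None = None,
) -> ModuleAssignment:
    """Cut the average-linkage TOM dendrogram into modules.

    Clustering runs on the dissimilarity 1 - TOM.  With ``cut_height=None``
    the cut height is chosen adaptively: every candidate height between
    consecutive merge levels is scored by the weighted modularity of the
    resulting partition on the TOM graph (diagonal excluded) and the best
    height wins — a branch-sensitive criterion that isolates tight branches
    instead of relying on a fixed fraction of the tree height.  A fixed
    height can be given instead.  Clusters smaller than ``min_module_size``
    are merged into label 0 (unassigned); surviving modules are labelled
    1, 2, ... by decreasing size.
    """
    t = np.asarray(t, dtype=float)
    m = t.shape[0]
    if variant_ids is None:
        variant_ids = [str(k) for k in range(m)]
    if min_module_size < 2:
        raise ValueError("min_module_size must be >= 2")

    warns: list[str] = []
    if m < min_module_size:
        msg = f"only {m} variants (< min_module_size={min_module_size}); all unassigned"
        warnings.warn(msg)
        return ModuleAssignment(
            labels=pd.Series(0, index=pd.Index(variant_ids, name="id")),
            warnings_=[msg],
        )

    off = t - np.diag(np.diag(t))
    if off.max() <= 0:  # no connections at all: nothing to cluster
        return ModuleAssignment(
            labels=pd.Series(0, index=pd.Index(variant_ids, name="id")),
            warnings_=["empty network: all variants unassigned"],
        )

    dissim = 1.0 - t
    np.fill_diagonal(dissim, 0.0)
    Z = linkage(squareform(dissim, checks=False), method="average")
    if cut_height is None:
        w = t.copy()
        np.fill_diagonal(w, 0.0)
        raw = _adaptive_cut(w, Z, min_module_size)
    else:
        raw = fcluster(Z, t=cut_height, criterion="distance")
    w = t.copy()
    np.fill_diagonal(w, 0.0)
    raw = _refine_membership(w, raw, min_module_size)

    sizes = pd.Series(raw).value_counts()
    big = [c for c in sizes.index if c != 0 and sizes[c] >= min_module_size]
    # relabel by decreasing size; ties broken by first appearance for determinism
    order = sorted(big, key=lambda c: (-sizes[c], np.argmax(raw == c)))
    labels = np.zeros(m, dtype=int)
    for new, old in enumerate(order, start=1):
        labels[raw == old] = new
    return ModuleAssignment(
        labels=pd.Series(labels, index=pd.Index(variant_ids, name="id")),
        linkage=Z,
        warnings_=warns,
    )


def _eigensnp(X: np.ndarray) -> np.ndarray:
    """First principal component score of a standardized dosage submatrix.

    Missing calls are mean-imputed per variant; the score's sign is anchored
    so it correlates positively with the mean dosage across members.
    """
    X = np.array(X, dtype=float)
    for c in range(X.shape[1]):
        col = X[:, c]
        mu = np.nanmean(col)
        col[~np.isfinite(col)] = mu
        sd = col.std()
        X[:, c] = (col - mu) / sd if sd > 0 else 0.0
    U, S, _ = np.linalg.svd(X, full_matrices=False)
    score = U[:, 0] * S[0]
    anchor = X.mean(axis=1)
    if anchor.std() > 0 and np.corrcoef(score, anchor)[0, 1] < 0:
        score = -score
    return score


def module_trait_correlation(
    modules: ModuleAssignment,
    g: GenotypeTable,
    y: np.ndarray,
    summary: str = "mean",
) -> ModuleAssignment:
    """Correlate each module's summary genotype with the phenotype.

    The default summary is the mean dosage across module members: unlike
    co-expression modules, variants grouped by *interaction* need not be
    mutually correlated, so the first principal component of their dosages
    can point in an arbitrary noise direction — the mean aggregates the
    members' marginal trait associations robustly.  ``summary="pc1"`` uses
    the eigen-SNP (first PC of standardized member dosages) instead; both
    reduce to the single variant's dosage for a one-member module.  Pearson
    r and its p-value against ``y`` are stored in ``module_stats``.
    """
    if summary not in ("mean", "pc1"):
        raise ValueError(f"summary must be 'mean' or 'pc1', got {summary!r}")
    y = np.asarray(y, dtype=float)
    id_to_col = {v: k for k, v in enumerate(g.variants["id"])}
    rows = []
    for label in sorted(set(modules.labels) - {0}):
        member_ids = modules.members(label)
        cols = [id_to_col[v] for v in member_ids if v in id_to_col]
        X = g.dosage[:, cols]
        if X.shape[1] == 1:
            score = np.where(np.isfinite(X[:, 0]), X[:, 0], np.nanmean(X[:, 0]))
        elif summary == "mean":
            score = np.nanmean(X, axis=1)
        else:
            score = _eigensnp(X)
        ok = np.isfinite(y)
        if score[ok].std() == 0:
            r, p = 0.0, 1.0
        else:
            r, p = stats.pearsonr(score[ok], y[ok])
        rows.append({"module": label, "size": len(cols), "r": r, "p": p})
    modules.module_stats = pd.DataFrame(rows)
    return modules
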