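"""Exhaustive pairwise interaction scans.

For every retained variant pair (i, j) the heterogeneity model

    y = mu + b1*snp_i + b2*snp_j + b3*(snp_i x snp_j) + e

is fitted — by closed-form least squares for a continuous trait, or by a
binomial GLM (probit link by default, reading case status as a thresholded
liability) for a binary one.  The interaction coefficient b3 and its test
are the quantities of interest; everything downstream (network, modules,
plots) is built from them.

Under the 0/1/2 minor-allele encoding the opposite hypothesis — interaction
between the minor allele at one locus and the major allele at the other —
corresponds to reversing the homozygote labels at the second locus
(dosage -> 2 - dosage).  Because the reversed design spans the same column
space (gi*(2-gj) = 2*gi - gi*gj), the reversed model is an exact
reparameterization of the standard one: the fit, the interaction p-value
and the standard error are identical, and the interaction coefficient only
flips sign.  Both parameterizations are therefore always available; the one
in which the interaction coefficient is positive is reported as the pair's
orientation (minor-minor vs minor-major synergy), which is also the
parameterization with the smaller p-value whenever floating point breaks
the exact tie.  The gradient encoding (1/1.5/2) involves all four alleles
already, so it has a single orientation.

The scan is embarrassingly parallel: the pair index space is split into
chunks handled by independent workers, and results are identical whatever
the worker count or chunk size.
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
from joblib import Parallel, delayed
from scipy import stats

from .genotypes import GenotypeTable
from .glm import fit_binomial

__all__ = [
    "PairResult",
    "EpistasisTable",
    "fit_pair_linear",
    "fit_pair_glm",
    "fit_pair_bidirectional",
    "run_all_pairs",
    "count_pairs",
    "round_sig",
    "runtime_probe",
]

# smallest p-value reported; keeps -log10(p) finite for exact fits
_P_FLOOR = 1e-300
_RANK_TOL = 1e-10
_MIN_N_LINEAR = 5
_MIN_N_GLM = 10

STATUS_OK = "ok"
STATUS_DEGENERATE = "degenerate"
STATUS_UNSTABLE = "unstable"

ORIENT_STANDARD = "minor_dominant"
ORIENT_REVERSED = "minor_reversed_j"
ORIENT_GRADIENT = "gradient"


@dataclass
class PairResult:
    i: int
    j: int
    mu: float
    beta1: float
    beta2: float
    beta3: float
    se3: float
    p3: float
    encoding_used: str
    n_used: int
    status: str = STATUS_OK

    @property
    def neglog_p3(self) -> float:
        return -np.log10(self.p3) if np.isfinite(self.p3) else np.nan


class PairCount(NamedTuple):
    """Exact C(n, 2) and the n^2/2 order-of-magnitude approximation."""

    exact: int
    approx: float


def count_pairs(n_variants: int) -> PairCount:
    """Number of unordered variant pairs an exhaustive scan must fit."""
    n = int(n_variants)
    if n < 0:
        raise ValueError("n_variants must be non-negative")
    return PairCount(n * (n - 1) // 2, n * n / 2.0)


def round_sig(x: float, digits: int = 2) -> float:
    """Round to significant figures, halves away from zero (print convention)."""
    from decimal import ROUND_HALF_UP, Decimal

    x = float(x)
    if x == 0 or not np.isfinite(x):
        return x
    shift = digits - 1 - math.floor(math.log10(abs(x)))
    d = Decimal(repr(x)).scaleb(shift).quantize(Decimal(1), rounding=ROUND_HALF_UP)
    return float(d.scaleb(-shift))


# ---------------------------------------------------------------------------
# batched closed-form least squares on the 4-column design [1, a, b, a*b]
# ---------------------------------------------------------------------------

def _batch_linear(Y: np.ndarray, A: np.ndarray, B: np.ndarray) -> dict:
    """Fit the interaction model for P pairs at once via normal equations.

    ``A``/``B`` are (n, P) encoded dosages for the first/second locus of each
    pair; ``Y`` is (n,) or (n, P).  Missing values are removed case-wise per
    pair.  Returns per-pair coefficient arrays plus a degeneracy mask for
    rank-deficient or undersized designs.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = np.broadcast_to(Y[:, None], A.shape)
    P = A.shape[1]

    valid = np.isfinite(A) & np.isfinite(B) & np.isfinite(Y)
    Az = np.where(valid, A, 0.0)
    Bz = np.where(valid, B, 0.0)
    Yz = np.where(valid, Y, 0.0)
    W = Az * Bz

    n_used = valid.sum(axis=0).astype(float)
    Sa = Az.sum(axis=0)
    Sb = Bz.sum(axis=0)
    Sw = W.sum(axis=0)
    Saa = (Az * Az).sum(axis=0)
    Sbb = (Bz * Bz).sum(axis=0)
    Saw = (Az * W).sum(axis=0)
    Sbw = (Bz * W).sum(axis=0)
    Sww = (W * W).sum(axis=0)
    Sy = Yz.sum(axis=0)
    Say = (Az * Yz).sum(axis=0)
    Sby = (Bz * Yz).sum(axis=0)
    Swy = (W * Yz).sum(axis=0)
    Syy = (Yz * Yz).sum(axis=0)

    XtX = np.empty((P, 4, 4))
    XtX[:, 0, 0] = n_used
    XtX[:, 0, 1] = XtX[:, 1, 0] = Sa
    XtX[:, 0, 2] = XtX[:, 2, 0] = Sb
    XtX[:, 0, 3] = XtX[:, 3, 0] = Sw
    XtX[:, 1, 1] = Saa
    XtX[:, 1, 2] = XtX[:, 2, 1] = Sw  # sum(a*b)
    XtX[:, 1, 3] = XtX[:, 3, 1] = Saw
    XtX[:, 2, 2] = Sbb
    XtX[:, 2, 3] = XtX[:, 3, 2] = Sbw
    XtX[:, 3, 3] = Sww
    Xty = np.stack([Sy, Say, Sby, Swy], axis=1)

    eig = np.linalg.eigvalsh(XtX)
    degenerate = (n_used < _MIN_N_LINEAR) | (eig[:, 0] <= _RANK_TOL * np.maximum(eig[:, -1], 1.0))

    beta = np.full((P, 4), np.nan)
    se3 = np.full(P, np.nan)
    p3 = np.full(P, np.nan)
    good = ~degenerate
    if good.any():
        inv = np.linalg.inv(XtX[good])
        bg = np.einsum("pij,pj->pi", inv, Xty[good])
        beta[good] = bg
        rss = np.clip(Syy[good] - np.einsum("pi,pi->p", bg, Xty[good]), 0.0, None)
        df = n_used[good] - 4
        sigma2 = rss / df
        se = np.sqrt(np.clip(sigma2 * inv[:, 3, 3], 0.0, None))
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = np.where(
                se > 0, bg[:, 3] / se, np.where(bg[:, 3] == 0, 0.0, np.inf)
            )
        pg = 2.0 * stats.t.sf(np.abs(tstat), df)
        se3[good] = se
        p3[good] = np.maximum(pg, _P_FLOOR)

    return {
        "beta": beta,
        "se3": se3,
        "p3": p3,
        "n_used": n_used.astype(int),
        "degenerate": degenerate,
    }


def fit_pair_linear(y: np.ndarray, gi: np.ndarray, gj: np.ndarray) -> PairResult:
    """Closed-form least-squares fit of the interaction model for one pair."""
    res = _batch_linear(np.asarray(y, float), np.asarray(gi, float)[:, None],
                        np.asarray(gj, float)[:, None])
    status = STATUS_DEGENERATE if res["degenerate"][0] else STATUS_OK
    b = res["beta"][0]
    return PairResult(
        i=0, j=1, mu=b[0], beta1=b[1], beta2=b[2], beta3=b[3],
        se3=res["se3"][0], p3=res["p3"][0], encoding_used=ORIENT_STANDARD,
        n_used=int(res["n_used"][0]), status=status,
    )


def fit_pair_glm(
    y01: np.ndarray,
    gi: np.ndarray,
    gj: np.ndarray,
    link: str = "probit",
    covariates: np.ndarray | None = None,
) -> PairResult:
    """Binomial GLM fit of the interaction model for one pair.

    The interaction coefficient is tested with a Wald z-test.  Perfect
    separation or non-convergence flags the pair "unstable" (p3 missing);
    rank-deficient designs flag it "degenerate".
    """
    y01 = np.asarray(y01, dtype=float)
    gi = np.asarray(gi, dtype=float)
    gj = np.asarray(gj, dtype=float)
    ok = np.isfinite(y01) & np.isfinite(gi) & np.isfinite(gj)
    if covariates is not None:
        covariates = np.asarray(covariates, dtype=float)
        if covariates.ndim == 1:
            covariates = covariates[:, None]
        ok &= np.all(np.isfinite(covariates), axis=1)
    yv, a, b = y01[ok], gi[ok], gj[ok]
    n = int(ok.sum())

    uniq = np.unique(yv)
    if not np.all(np.isin(uniq, (0.0, 1.0))):
        raise ValueError("binary phenotype must be coded 0/1")
    if uniq.size < 2:
        raise ValueError("binary phenotype has a single class; cannot fit GLM")

    def _flagged(status):
        return PairResult(0, 1, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan,
                          ORIENT_STANDARD, n, status)

    X = np.column_stack([np.ones(n), a, b, a * b])
    if covariates is not None:
        X = np.column_stack([X, covariates[ok]])
    if n < _MIN_N_GLM or np.linalg.matrix_rank(X) < X.shape[1]:
        return _flagged(STATUS_DEGENERATE)

    fit = fit_binomial(yv, X, link=link)
    if not fit.converged:
        return _flagged(STATUS_UNSTABLE)
    return PairResult(
        i=0, j=1, mu=fit.params[0], beta1=fit.params[1], beta2=fit.params[2],
        beta3=fit.params[3], se3=fit.bse[3],
        p3=max(fit.pvalues[3], _P_FLOOR),
        encoding_used=ORIENT_STANDARD, n_used=n, status=STATUS_OK,
    )


def _reverse(gj: np.ndarray) -> np.ndarray:
    """Swap the homozygote labels of a 0/1/2 dosage vector (missing stays missing)."""
    return 2.0 - gj


def _reversed_coefficients(mu, beta1, beta2, beta3):
    """Reparameterize the fitted model under gj -> 2 - gj.

    Substituting gj = 2 - gj' gives mu' = mu + 2*b2, b1' = b1 + 2*b3,
    b2' = -b2, b3' = -b3; the residuals, the interaction standard error and
    its p-value are unchanged because the two designs span the same space.
    """
    return mu + 2.0 * beta2, beta1 + 2.0 * beta3, -beta2, -beta3


def fit_pair_bidirectional(
    y: np.ndarray,
    gi: np.ndarray,
    gj: np.ndarray,
    base_scheme: str = "minor_dominant",
    model_kind: str = "linear",
    link: str = "probit",
    covariates: np.ndarray | None = None,
) -> PairResult:
    """Fit the pair and report it in its better label orientation.

    Under the 0/1/2 scheme the model is considered in both homozygote-label
    orientations of the second locus.  The two are exact reparameterizations
    of each other (identical fit and interaction p-value, sign-flipped
    interaction coefficient), so the reversed fit is obtained analytically
    from the standard one and the orientation with the positive — hence
    never the larger-p — interaction coefficient is reported, recorded in
    ``encoding_used``.  The gradient scheme has a single orientation.
    """
    if model_kind == "linear":
        res = fit_pair_linear(y, gi, gj)
    elif model_kind == "glm":
        res = fit_pair_glm(y, gi, gj, link=link, covariates=covariates)
    else:
        raise ValueError(f"unknown model_kind {model_kind!r}")
    if base_scheme == "gradient":
        res.encoding_used = ORIENT_GRADIENT
        return res
    if res.status == STATUS_OK and res.beta3 < 0:
        res.mu, res.beta1, res.beta2, res.beta3 = _reversed_coefficients(
            res.mu, res.beta1, res.beta2, res.beta3
        )
        res.encoding_used = ORIENT_REVERSED
    else:
        res.encoding_used = ORIENT_STANDARD
    return res


# ---------------------------------------------------------------------------
# full scan
# ---------------------------------------------------------------------------

@dataclass
class EpistasisTable:
    """Fitted interaction results for a set of variant pairs.

    ``pairs`` holds one row per unordered pair with the coefficients, the
    interaction test, the winning encoding orientation and a status flag;
    ``variants`` carries the variant metadata of the scanned table so plots
    can place pairs on the genome.
    """

    pairs: pd.DataFrame
    model_kind: str
    variants: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    PAIR_COLUMNS = [
        "i", "j", "snp_i", "snp_j", "chr_i", "chr_j", "pos_i", "pos_j",
        "mu", "beta1", "beta2", "beta3", "se3", "p3", "neglog_p3",
        "orientation", "n_used", "status",
    ]

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def ok_pairs(self) -> pd.DataFrame:
        return self.pairs[self.pairs["status"] == STATUS_OK]

    def to_tsv(self, path) -> Path:
        path = Path(path)
        self.pairs.to_csv(path, sep="\t", index=False)
        return path

    @classmethod
    def from_tsv(cls, path, variants: pd.DataFrame | None = None,
                 model_kind: str = "linear") -> "EpistasisTable":
        pairs = pd.read_csv(path, sep="\t", dtype={"chr_i": str, "chr_j": str})
        if variants is None:
            variants = _variants_from_pairs(pairs)
        return cls(pairs=pairs, model_kind=model_kind, variants=variants)


def _variants_from_pairs(pairs: pd.DataFrame) -> pd.DataFrame:
    left = pairs[["snp_i", "chr_i", "pos_i"]].rename(
        columns={"snp_i": "id", "chr_i": "chrom", "pos_i": "pos"})
    right = pairs[["snp_j", "chr_j", "pos_j"]].rename(
        columns={"snp_j": "id", "chr_j": "chrom", "pos_j": "pos"})
    return (
        pd.concat([left, right]).drop_duplicates("id").reset_index(drop=True)
    )


def _pair_index_arrays(m: int, pairs: Iterable[tuple[int, int]] | None):
    if pairs is None:
        ii, jj = np.triu_indices(m, k=1)
        return ii.astype(np.int64), jj.astype(np.int64)
    arr = np.asarray(list(pairs), dtype=np.int64)
    if arr.size == 0:
        raise ValueError("empty pair list")
    ii, jj = np.minimum(arr[:, 0], arr[:, 1]), np.maximum(arr[:, 0], arr[:, 1])
    if np.any(ii == jj):
        raise ValueError("pair list contains self-pairs")
    return ii, jj


def _linear_chunk(y, G, ii, jj, bidirectional):
    res = _batch_linear(y, G[:, ii], G[:, jj])
    orient = np.full(ii.size, ORIENT_STANDARD, dtype=object)
    if bidirectional:
        # report each pair in the label orientation with a positive
        # interaction coefficient (exact reparameterization; see module docs)
        use_rev = ~res["degenerate"] & (res["beta"][:, 3] < 0)
        b = res["beta"]
        mu2, b12, b22, b32 = _reversed_coefficients(b[:, 0], b[:, 1], b[:, 2], b[:, 3])
        rev_beta = np.stack([mu2, b12, b22, b32], axis=1)
        res["beta"] = np.where(use_rev[:, None], rev_beta, b)
        orient[use_rev] = ORIENT_REVERSED
    return res, orient


def _glm_chunk(y, G, ii, jj, bidirectional, link, covariates):
    rows = []
    for a, b in zip(ii, jj):
        if bidirectional:
            r = fit_pair_bidirectional(y, G[:, a], G[:, b], model_kind="glm",
                                       link=link, covariates=covariates)
        else:
            r = fit_pair_glm(y, G[:, a], G[:, b], link=link, covariates=covariates)
        rows.append(r)
    res = {
        "beta": np.array([[r.mu, r.beta1, r.beta2, r.beta3] for r in rows]),
        "se3": np.array([r.se3 for r in rows]),
        "p3": np.array([r.p3 for r in rows]),
        "n_used": np.array([r.n_used for r in rows]),
        "degenerate": np.array([r.status != STATUS_OK for r in rows]),
    }
    orient = np.array([r.encoding_used for r in rows], dtype=object)
    statuses = np.array([r.status for r in rows], dtype=object)
    return res, orient, statuses


def _chunk_frame(g, ii, jj, res, orient, statuses=None):
    with np.errstate(divide="ignore"):
        neglog = -np.log10(res["p3"])
    if statuses is None:
        statuses = np.where(res["degenerate"], STATUS_DEGENERATE, STATUS_OK)
    ids = g.variants["id"].to_numpy()
    chrom = g.variants["chrom"].astype(str).to_numpy()
    pos = g.variants["pos"].to_numpy()
    return pd.DataFrame(
        {
            "i": ii, "j": jj,
            "snp_i": ids[ii], "snp_j": ids[jj],
            "chr_i": chrom[ii], "chr_j": chrom[jj],
            "pos_i": pos[ii], "pos_j": pos[jj],
            "mu": res["beta"][:, 0], "beta1": res["beta"][:, 1],
            "beta2": res["beta"][:, 2], "beta3": res["beta"][:, 3],
            "se3": res["se3"], "p3": res["p3"], "neglog_p3": neglog,
            "orientation": orient, "n_used": res["n_used"],
            "status": statuses,
        }
    )


def _run_chunk(g, y, ii, jj, model_kind, bidirectional, link, covariates):
    if model_kind == "linear":
        res, orient = _linear_chunk(y, g.dosage, ii, jj, bidirectional)
        return _chunk_frame(g, ii, jj, res, orient)
    res, orient, statuses = _glm_chunk(y, g.dosage, ii, jj, bidirectional, link, covariates)
    return _chunk_frame(g, ii, jj, res, orient, statuses)


def run_all_pairs(
    g: GenotypeTable,
    y: np.ndarray,
    model_kind: str = "linear",
    scheme: str = "minor_dominant",
    n_workers: int = 1,
    chunk_size: int = 20000,
    pairs: Iterable[tuple[int, int]] | None = None,
    link: str = "probit",
    covariates: np.ndarray | None = None,
    chunk_dir=None,
) -> EpistasisTable:
    """Fit the interaction model for all C(m, 2) pairs (or a supplied list).

    The pair space is split into ``chunk_size`` chunks run by ``n_workers``
    joblib workers; output is merged in chunk order, so results do not
    depend on the worker count or chunk size.  If ``chunk_dir`` is given,
    each completed chunk is written there as TSV and existing chunk files
    are reused, making an interrupted scan resumable.
    """
    if g.n_variants < 2:
        raise ValueError("need at least 2 variants for a pair scan")
    if n_workers < 1 or chunk_size < 1:
        raise ValueError("n_workers and chunk_size must be positive")
    if model_kind not in ("linear", "glm"):
        raise ValueError(f"unknown model_kind {model_kind!r}")
    y = np.asarray(y, dtype=float)
    if y.shape[0] != g.n_samples:
        raise ValueError("phenotype length does not match sample count")

    if scheme == "gradient":
        from .genotypes import encode

        g = encode(g, "gradient")
        bidirectional = False
    else:
        bidirectional = True

    ii, jj = _pair_index_arrays(g.n_variants, pairs)
    n_pairs = ii.size
    starts = list(range(0, n_pairs, chunk_size))

    if chunk_dir is not None:
        chunk_dir = Path(chunk_dir)
        chunk_dir.mkdir(parents=True, exist_ok=True)

    def _chunk_path(k):
        return chunk_dir / f"chunk_{k:06d}.tsv"

    def _do(k, s):
        e = min(s + chunk_size, n_pairs)
        if chunk_dir is not None and _chunk_path(k).exists():
            return pd.read_csv(_chunk_path(k), sep="\t", dtype={"chr_i": str, "chr_j": str})
        frame = _run_chunk(g, y, ii[s:e], jj[s:e], model_kind, bidirectional,
                           link, covariates)
        if chunk_dir is not None:
            tmp = _chunk_path(k).with_suffix(".tmp")
            frame.to_csv(tmp, sep="\t", index=False)
            tmp.rename(_chunk_path(k))
        return frame

    if n_workers == 1:
        frames = [_do(k, s) for k, s in enumerate(starts)]
    else:
        frames = Parallel(n_jobs=n_workers)(
            delayed(_do)(k, s) for k, s in enumerate(starts)
        )
    table = pd.concat(frames, ignore_index=True)
    return EpistasisTable(
        pairs=table,
        model_kind=model_kind,
        variants=g.variants.copy(),
        provenance={
            "scheme": scheme,
            "bidirectional": bidirectional,
            "link": link if model_kind == "glm" else None,
            "n_samples": g.n_samples,
        },
    )


@dataclass
class RuntimeProbe:
    n_variants: int
    n_samples: int
    n_pairs: int
    elapsed_s: float
    models_per_second: float
    projected_total_s: float
    projected_for: int


def runtime_probe(
    n_variants: int = 500,
    n_samples: int = 500,
    n_workers: int = 1,
    seed: int = 0,
    target_variants: int | None = None,
    model_kind: str = "linear",
) -> RuntimeProbe:
    """Time a small random scan and extrapolate to a target problem size.

    Simulates ``n_variants`` independent variants and a noise phenotype,
    runs the full pair scan, and reports models/second plus the projected
    wall time for ``target_variants`` (default: the probe size itself).
    The numbers are hardware-dependent by construction.
    """
    from .simulate import SimulationSpec, simulate_genotypes

    spec = SimulationSpec(n_samples=n_samples, n_variants=n_variants, seed=seed)
    g = simulate_genotypes(spec)
    rng = np.random.default_rng(seed + 1)
    y = rng.normal(size=n_samples)
    t0 = time.perf_counter()
    tbl = run_all_pairs(g, y, model_kind=model_kind, n_workers=n_workers)
    elapsed = time.perf_counter() - t0
    rate = len(tbl) / elapsed
    target = target_variants if target_variants is not None else n_variants
    projected = count_pairs(target).exact / rate
    return RuntimeProbe(
        n_variants=n_variants, n_samples=n_samples, n_pairs=len(tbl),
        elapsed_s=elapsed, models_per_second=rate,
        projected_total_s=projected, projected_for=target,
    )
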