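"""Phenotype covariate adjustment and single-SNP association pre-filtering.

Continuous phenotypes are adjusted for non-genetic fixed effects once, up
front, by taking residuals of an ordinary least-squares fit on the
covariates (the grand mean is added back so the trait keeps its original
scale).  Binary traits cannot be adjusted this way; their covariates are
carried into the per-pair GLM design instead.

The optional association pre-filter fits ``y = mu + beta * snp`` per variant
and keeps variants whose main-effect p-value passes a user threshold —
variants with no marginal effect are unlikely to carry detectable
interactions, and the filter shrinks the quadratic pair space.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GenotypeTable
from .glm import fit_probit

logger = logging.getLogger(__name__)

__all__ = ["adjust_phenotype", "gwas_filter", "align_phenotype"]


def align_phenotype(g: GenotypeTable, pheno: pd.DataFrame, phenotype: str) -> pd.DataFrame:
    """Inner-join a phenotype table onto the genotype sample order.

    Returns the phenotype rows reordered to ``g.samples``; raises if any
    genotyped sample is missing a phenotype record.
    """
    df = pheno.set_index(pheno["sample_id"].astype(str))
    missing = [s for s in g.samples if s not in df.index]
    if missing:
        raise KeyError(
            f"{len(missing)} genotyped sample(s) missing from the phenotype "
            f"table (first: {missing[0]})"
        )
    out = df.loc[[str(s) for s in g.samples]].reset_index(drop=True)
    if phenotype not in out.columns:
        raise KeyError(f"phenotype column {phenotype!r} not in table")
    return out


def _design_from_covariates(pheno: pd.DataFrame, covariate_names: list[str]) -> pd.DataFrame:
    cols = {}
    for name in covariate_names:
        if name not in pheno.columns:
            raise KeyError(f"covariate {name!r} not in phenotype table")
        col = pheno[name]
        if pd.api.types.is_numeric_dtype(col):
            cols[name] = col.astype(float)
        else:  # categorical -> indicator contrasts, first level dropped
            dummies = pd.get_dummies(col, prefix=name, drop_first=True, dtype=float)
            for c in dummies.columns:
                cols[c] = dummies[c]
    return pd.DataFrame(cols, index=pheno.index)


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    """Columns (after the intercept) lying in the span of the preceding ones."""
    bad, kept = [], [np.ones(X.shape[0])]
    for j, name in enumerate(names):
        basis = np.column_stack(kept + [X[:, j]])
        if np.linalg.matrix_rank(basis) < basis.shape[1]:
            bad.append(name)
        else:
            kept.append(X[:, j])
    return bad


def adjust_phenotype(
    pheno: pd.DataFrame,
    phenotype: str,
    covariate_names: list[str] | None = None,
) -> pd.DataFrame:
    """Regress non-genetic fixed effects out of a continuous phenotype.

    Returns a copy of ``pheno`` with an ``adjusted`` column holding the OLS
    residual plus the grand mean.  Samples with a missing phenotype or
    covariate are dropped (with a logged count).  Binary 0/1 phenotypes are
    rejected: linear residuals are not a valid adjustment there, and the GLM
    path accepts covariates directly.
    """
    covariate_names = covariate_names or []
    y_raw = pd.to_numeric(pheno[phenotype], errors="coerce")
    vals = y_raw.dropna().unique()
    if len(vals) and set(np.unique(vals)) <= {0.0, 1.0}:
        raise ValueError(
            "phenotype looks binary (0/1); residual adjustment is invalid — "
            "pass covariates to the GLM interaction model instead"
        )

    X_df = _design_from_covariates(pheno, covariate_names)
    ok = y_raw.notna()
    for c in X_df.columns:
        ok &= X_df[c].notna()
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("adjust_phenotype: dropped %d sample(s) with missing values", n_dropped)

    out = pheno.copy()
    y = y_raw[ok].to_numpy(float)
    if not X_df.shape[1]:
        out.loc[ok, "adjusted"] = y
        out.loc[~ok, "adjusted"] = np.nan
        return out

    X = X_df.loc[ok].to_numpy(float)
    design = np.column_stack([np.ones(len(y)), X])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        bad = _collinear_columns(X, list(X_df.columns))
        raise ValueError(f"covariate design is rank deficient; collinear columns: {bad}")
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    out.loc[ok, "adjusted"] = resid + y.mean()
    out.loc[~ok, "adjusted"] = np.nan
    return out


def gwas_filter(
    g: GenotypeTable,
    y: np.ndarray,
    p_threshold: float,
    model_kind: str = "linear",
) -> tuple[GenotypeTable, pd.DataFrame]:
    """Keep variants whose single-SNP main effect has p <= p_threshold.

    For a continuous trait each variant is tested with simple least squares
    ``y = mu + beta * g``; a binary trait uses the probit GLM.  Missing calls
    are dropped per variant.  Returns the reduced table and a per-variant
    report (id, beta, p).
    """
    if not 0.0 < p_threshold <= 1.0:
        raise ValueError(f"p_threshold must be in (0, 1], got {p_threshold}")
    y = np.asarray(y, dtype=float)
    if y.shape[0] != g.n_samples:
        raise ValueError("phenotype length does not match sample count")

    betas = np.full(g.n_variants, np.nan)
    pvals = np.ones(g.n_variants)
    for v in range(g.n_variants):
        x = g.dosage[:, v]
        ok = np.isfinite(x) & np.isfinite(y)
        xv, yv = x[ok], y[ok]
        n = xv.size
        if n < 4 or np.ptp(xv) == 0:
            continue
        if model_kind == "linear":
            xc = xv - xv.mean()
            yc = yv - yv.mean()
            sxx = xc @ xc
            beta = (xc @ yc) / sxx
            resid = yc - beta * xc
            df = n - 2
            sigma2 = (resid @ resid) / df
            se = np.sqrt(sigma2 / sxx)
            t = beta / se if se > 0 else np.inf
            p = 2 * stats.t.sf(abs(t), df)
        elif model_kind == "glm":
            fit = fit_probit(yv, np.column_stack([np.ones(n), xv]))
            if not fit.converged:
                continue
            beta, p = fit.params[1], fit.pvalues[1]
        else:
            raise ValueError(f"unknown model_kind {model_kind!r}")
        betas[v], pvals[v] = beta, p

    report = pd.DataFrame(
        {"id": g.variants["id"], "beta": betas, "p": pvals}
    )
    keep = np.flatnonzero(pvals <= p_threshold)
    if keep.size == 0:
        raise ValueError(
            f"no variant passed the association filter at p <= {p_threshold}"
        )
    return g.take_variants(keep), report
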