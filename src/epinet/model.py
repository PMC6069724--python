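"""Model/Results interface for genome-wide interaction scans.

:class:`EpistasisScan` bundles genotypes, a phenotype and the modelling
choices (encoding scheme, linear vs binomial GLM, covariates); ``fit()``
runs the exhaustive pair scan and returns an :class:`EpistasisScanResults`
carrying the fitted pair table, with the network/module analysis and the
standard plots hanging off it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import network as _network
from . import viz as _viz
from .epistasis import EpistasisTable, count_pairs, run_all_pairs
from .genotypes import GenotypeTable, read_ped_tped, read_phenotype_table
from .preprocess import adjust_phenotype, align_phenotype

__all__ = ["EpistasisScan", "EpistasisScanResults", "NetworkResults"]


class EpistasisScan:
    """Pairwise SNP-SNP interaction model for one phenotype.

    Parameters
    ----------
    genotypes : GenotypeTable
        QC'd (and optionally LD-collapsed) genotypes.
    phenotype : array-like
        Trait values aligned to ``genotypes.samples``; continuous traits are
        fitted by least squares, binary 0/1 traits by a binomial GLM.
    covariates : ndarray, optional
        Extra design columns for the GLM path (continuous traits should be
        pre-adjusted with :func:`epinet.preprocess.adjust_phenotype`).
    scheme : {"minor_dominant", "gradient"}
        Genotype encoding; under ``minor_dominant`` both label orientations
        are tested per pair and the better one kept.
    """

    def __init__(
        self,
        genotypes: GenotypeTable,
        phenotype,
        covariates: np.ndarray | None = None,
        model_kind: str = "auto",
        scheme: str = "minor_dominant",
        link: str = "probit",
    ):
        self.genotypes = genotypes
        self.phenotype = np.asarray(phenotype, dtype=float)
        if self.phenotype.shape[0] != genotypes.n_samples:
            raise ValueError("phenotype length does not match sample count")
        if model_kind == "auto":
            vals = np.unique(self.phenotype[np.isfinite(self.phenotype)])
            model_kind = "glm" if set(vals) <= {0.0, 1.0} else "linear"
        self.model_kind = model_kind
        self.scheme = scheme
        self.link = link
        self.covariates = covariates

    @classmethod
    def from_plink(
        cls,
        ped_path,
        tped_path,
        phenotype_path=None,
        phenotype: str = "phenotype",
        covariate_names: list[str] | None = None,
        adjust: bool = True,
        **kwargs,
    ) -> "EpistasisScan":
        """Build a scan straight from ped/tped (+ phenotype table) files.

        With a phenotype table, continuous traits are covariate-adjusted up
        front (unless ``adjust=False``); without one, the ped file's
        phenotype column is used as-is.
        """
        g = read_ped_tped(ped_path, tped_path)
        if phenotype_path is not None:
            pheno = align_phenotype(g, read_phenotype_table(phenotype_path), phenotype)
            y_raw = pd.to_numeric(pheno[phenotype], errors="coerce")
            binary = set(y_raw.dropna().unique()) <= {0.0, 1.0}
            cov = None
            if binary:
                y = y_raw.to_numpy(float)
                if covariate_names:
                    from .preprocess import _design_from_covariates

                    cov = _design_from_covariates(pheno, covariate_names).to_numpy(float)
            elif adjust:
                y = adjust_phenotype(pheno, phenotype, covariate_names)["adjusted"].to_numpy(float)
            else:
                y = y_raw.to_numpy(float)
            return cls(g, y, covariates=cov, **kwargs)
        y = pd.to_numeric(pd.Series(g.sample_info["phenotype"]), errors="coerce").to_numpy(float)
        return cls(g, y, **kwargs)

    @property
    def n_pairs(self) -> int:
        return count_pairs(self.genotypes.n_variants).exact

    def fit(
        self,
        n_workers: int = 1,
        chunk_size: int = 20000,
        pairs=None,
        chunk_dir=None,
    ) -> "EpistasisScanResults":
        """Fit the interaction model for every pair and wrap the results."""
        tbl = run_all_pairs(
            self.genotypes,
            self.phenotype,
            model_kind=self.model_kind,
            scheme=self.scheme,
            n_workers=n_workers,
            chunk_size=chunk_size,
            pairs=pairs,
            link=self.link,
            covariates=self.covariates,
            chunk_dir=chunk_dir,
        )
        return EpistasisScanResults(self, tbl)


@dataclass
class NetworkResults:
    """Similarity/TOM matrices and module assignment derived from a scan."""

    similarity: _network.SimilarityMatrix
    adjacency: np.ndarray
    tom: np.ndarray
    modules: _network.ModuleAssignment

    @property
    def module_stats(self) -> pd.DataFrame | None:
        return self.modules.module_stats


class EpistasisScanResults:
    """Fitted pair table plus the network and visualization layers."""

    def __init__(self, model: EpistasisScan, table: EpistasisTable):
        self.model = model
        self.table = table

    @property
    def pairs(self) -> pd.DataFrame:
        return self.table.pairs

    def top_pairs(self, n: int = 10) -> pd.DataFrame:
        ok = self.table.ok_pairs
        return ok.nlargest(n, "neglog_p3")

    def build_network(
        self,
        power: float = 1.0,
        signed_mode: str = "unsigned",
        min_module_size: int = 10,
        cut_height: float | None = None,
        correlate_trait: bool = True,
        summary: str = "mean",
    ) -> NetworkResults:
        """Similarity -> adjacency -> TOM -> modules (-> trait correlation)."""
        s = _network.rescale_beta(self.table)
        a = _network.adjacency_from_similarity(s, power=power, signed_mode=signed_mode)
        t = _network.tom(a)
        modules = _network.detect_modules(
            t, variant_ids=s.variant_ids,
            min_module_size=min_module_size, cut_height=cut_height,
        )
        if correlate_trait:
            modules = _network.module_trait_correlation(
                modules, self.model.genotypes, self.model.phenotype, summary=summary
            )
        return NetworkResults(similarity=s, adjacency=a, tom=t, modules=modules)

    def plot_manhattan(self, ax=None):
        return _viz.pseudo_manhattan(self.table, ax=ax)

    def plot_chromosome_map(self, ax=None):
        return _viz.chrom_interaction_map(self.table, ax=ax)

    def plot_region_map(self, chrom_a, chrom_b, window_bp, ax=None):
        return _viz.pairwise_chr_map(self.table, chrom_a, chrom_b, window_bp, ax=ax)

    def summary(self, top: int = 5) -> str:
        """Plain-text summary of the scan: dimensions, status counts, top pairs."""
        t = self.table
        status = t.pairs["status"].value_counts().to_dict()
        lines = [
            "Pairwise interaction scan",
            "=" * 60,
            f"model:            {t.model_kind}"
            + (f" ({self.model.link} link)" if t.model_kind == "glm" else ""),
            f"encoding scheme:  {self.model.scheme}",
            f"samples:          {self.model.genotypes.n_samples}",
            f"variants:         {self.model.genotypes.n_variants}",
            f"pairs fitted:     {len(t)}"
            + f"  (ok {status.get('ok', 0)}, degenerate {status.get('degenerate', 0)},"
              f" unstable {status.get('unstable', 0)})",
            "",
            f"top {top} pairs by interaction significance:",
        ]
        cols = ["snp_i", "snp_j", "beta3", "se3", "p3", "orientation"]
        lines.append(self.top_pairs(top)[cols].to_string(index=False,
                                                         float_format=lambda v: f"{v:.4g}"))
        return "\n".join(lines)
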