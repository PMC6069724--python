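"""Synthetic genotypes and phenotypes with planted interaction effects.

The generator produces biallelic genotypes under Hardy-Weinberg equilibrium,
optional contiguous LD blocks with a calibrated within-block r-squared,
uniform missingness, and phenotypes built from the same heterogeneity model
the scan fits: planted main effects, planted pairwise interactions (in
either label orientation), covariate effects and Gaussian noise, with a
liability threshold for binary traits.  Everything is deterministic under
the spec's seed, and the planted truth is returned as a first-class record
so recovery tests are self-documenting.

LD blocks are made by copy-with-resample noise: every block member copies a
shared latent genotype with probability r2_target**(1/4) per sample and
otherwise redraws from Hardy-Weinberg at the same allele frequency.  Two
members then share the latent draw with probability sqrt(r2_target), so the
expected pairwise correlation is sqrt(r2_target) and the pairwise r-squared
matches the target symmetrically across all member pairs, while the allele
frequency is preserved exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import GenotypeTable, write_ped_tped

__all__ = ["SimulationSpec", "simulate_genotypes", "simulate_phenotype", "write_fixture"]

_ALLELE_PAIRS = [("A", "G"), ("C", "T"), ("A", "C"), ("G", "T")]


@dataclass
class SimulationSpec:
    """Parameters of one synthetic dataset.

    ``ld_block_spec`` is a list of (block_length, r2_target) tuples; blocks
    are laid down from the start of each chromosome until variants run out,
    remaining variants being independent.  ``planted_pairs`` holds
    (i, j, beta3, orientation) with orientation "standard" (gi * gj) or
    "reversed" (gi * (2 - gj)).
    """

    n_samples: int = 500
    n_variants: int = 200
    chromosomes: dict[str, int] | None = None  # chrom -> variant count
    maf_range: tuple[float, float] = (0.1, 0.5)
    ld_block_spec: list[tuple[int, float]] = field(default_factory=list)
    planted_pairs: list[tuple[int, int, float, str]] = field(default_factory=list)
    main_effects: list[tuple[int, float]] = field(default_factory=list)
    covariate_effects: list[tuple[str, float]] = field(default_factory=list)
    mu: float = 0.0
    noise_sd: float = 1.0
    trait_kind: str = "continuous"
    liability_threshold: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0

    def chromosome_layout(self) -> dict[str, int]:
        if self.chromosomes:
            if sum(self.chromosomes.values()) != self.n_variants:
                raise ValueError("per-chromosome counts must sum to n_variants")
            return dict(self.chromosomes)
        return {"1": self.n_variants}

    def validate(self) -> None:
        lo, hi = self.maf_range
        if not 0.0 < lo <= hi <= 0.5:
            raise ValueError("maf_range must lie within (0, 0.5]")
        for _, r2 in self.ld_block_spec:
            if not 0.0 <= r2 <= 1.0:
                raise ValueError(f"infeasible r2 target {r2}")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        for i, j, _, orient in self.planted_pairs:
            if not (0 <= i < self.n_variants and 0 <= j < self.n_variants):
                raise ValueError(f"planted pair ({i}, {j}) out of range")
            if orient not in ("standard", "reversed"):
                raise ValueError(f"unknown orientation {orient!r}")
        if self.trait_kind not in ("continuous", "binary"):
            raise ValueError(f"unknown trait_kind {self.trait_kind!r}")


def simulate_genotypes(spec: SimulationSpec) -> GenotypeTable:
    """Draw a GenotypeTable according to ``spec`` (deterministic under seed)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n, m = spec.n_samples, spec.n_variants

    mafs = rng.uniform(*spec.maf_range, size=m)
    complete = np.empty((n, m))
    # lay down LD blocks chromosome by chromosome
    layout = spec.chromosome_layout()
    chrom_of = np.empty(m, dtype=object)
    pos = np.empty(m, dtype=int)
    v = 0
    for chrom, count in layout.items():
        for k in range(count):
            chrom_of[v + k] = chrom
            pos[v + k] = (k + 1) * 1000
        v += count

    # block membership: consecutive runs within chromosomes
    block_of = np.full(m, -1, dtype=int)
    block_r2 = []
    if spec.ld_block_spec:
        v = 0
        spec_iter = iter(spec.ld_block_spec)
        for chrom, count in layout.items():
            start = v
            while v < start + count:
                try:
                    length, r2 = next(spec_iter)
                except StopIteration:
                    v = start + count
                    break
                length = min(length, start + count - v)
                for k in range(length):
                    block_of[v + k] = len(block_r2)
                block_r2.append(r2)
                v += length
            v = start + count

    latent: dict[int, np.ndarray] = {}
    for v in range(m):
        b = block_of[v]
        if b < 0:
            complete[:, v] = rng.binomial(2, mafs[v], size=n).astype(float)
            continue
        if b not in latent:
            latent[b] = rng.binomial(2, mafs[v], size=n).astype(float)
        else:
            mafs[v] = mafs[_block_seed(block_of, v)]
        copy = rng.random(n) < block_r2[b] ** 0.25
        fresh = rng.binomial(2, mafs[v], size=n).astype(float)
        complete[:, v] = np.where(copy, latent[b], fresh)

    dosage = complete.copy()
    if spec.missing_rate > 0:
        mask = rng.random((n, m)) < spec.missing_rate
        dosage[mask] = np.nan

    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=m)
    minor = [_ALLELE_PAIRS[k][0] for k in pair_idx]
    major = [_ALLELE_PAIRS[k][1] for k in pair_idx]

    # orient dosage to count the observed minor allele (ties broken toward
    # the lexicographically smaller allele), matching what a ped/tped
    # round trip through the reader would produce
    maf_obs = np.empty(m)
    call_rate = np.empty(m)
    for v in range(m):
        col = dosage[:, v]
        obs = col[np.isfinite(col)]
        call_rate[v] = obs.size / n
        freq = obs.sum() / (2 * obs.size) if obs.size else 0.0
        flip = freq > 0.5 or (freq == 0.5 and minor[v] > major[v])
        if flip:
            dosage[:, v] = 2.0 - dosage[:, v]
            complete[:, v] = 2.0 - complete[:, v]
            minor[v], major[v] = major[v], minor[v]
            freq = 1.0 - freq
        maf_obs[v] = min(freq, 1 - freq)

    variants = pd.DataFrame(
        {
            "id": [f"snp{v:05d}" for v in range(m)],
            "chrom": chrom_of,
            "pos": pos,
            "allele_minor": minor,
            "allele_major": major,
            "maf": maf_obs,
            "call_rate": call_rate,
        }
    )
    samples = [f"sample{s:05d}" for s in range(n)]
    g = GenotypeTable(variants, samples, dosage)
    g.complete_dosage = complete  # pre-masking matrix, used by simulate_phenotype
    return g


def _block_seed(block_of: np.ndarray, v: int) -> int:
    b = block_of[v]
    k = v
    while k > 0 and block_of[k - 1] == b:
        k -= 1
    return k


def simulate_phenotype(
    g: GenotypeTable, spec: SimulationSpec
) -> tuple[pd.DataFrame, dict]:
    """Build a phenotype from planted effects on ``g``.

    The phenotype is generated from the complete (pre-masking) dosage matrix
    when available, so missing calls are purely an observation process.
    Returns a phenotype table (sample_id, phenotype, covariates) and the
    ground-truth record of every planted effect.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed + 1_000_003)
    G = getattr(g, "complete_dosage", None)
    if G is None:
        G = np.where(np.isfinite(g.dosage), g.dosage, 0.0)
    n = g.n_samples

    liability = np.full(n, float(spec.mu))
    for i, beta in spec.main_effects:
        _check_polymorphic(G, i)
        liability += beta * G[:, i]
    for i, j, beta3, orient in spec.planted_pairs:
        _check_polymorphic(G, i)
        _check_polymorphic(G, j)
        gj = G[:, j] if orient == "standard" else 2.0 - G[:, j]
        liability += beta3 * G[:, i] * gj

    covariates = {}
    for name, effect in spec.covariate_effects:
        if name == "sex":
            cov = rng.integers(0, 2, size=n).astype(float)
        else:
            cov = rng.uniform(0, 1, size=n)
        covariates[name] = cov
        liability += effect * cov

    liability += rng.normal(scale=spec.noise_sd, size=n)

    if spec.trait_kind == "binary":
        y = (liability > spec.liability_threshold).astype(int)
    else:
        y = liability

    pheno = pd.DataFrame({"sample_id": g.samples, "phenotype": y, **covariates})
    truth = {
        "planted_pairs": [
            {"i": i, "j": j, "snp_i": g.variants["id"].iloc[i],
             "snp_j": g.variants["id"].iloc[j], "beta3": b, "orientation": o}
            for i, j, b, o in spec.planted_pairs
        ],
        "main_effects": [
            {"i": i, "snp": g.variants["id"].iloc[i], "beta": b}
            for i, b in spec.main_effects
        ],
        "covariate_effects": dict(spec.covariate_effects),
        "mu": spec.mu,
        "noise_sd": spec.noise_sd,
        "trait_kind": spec.trait_kind,
        "liability_threshold": spec.liability_threshold,
        "seed": spec.seed,
    }
    return pheno, truth


def _check_polymorphic(G: np.ndarray, i: int) -> None:
    if np.ptp(G[:, i]) == 0:
        raise ValueError(f"planted effect references monomorphic variant {i}")


def write_fixture(spec: SimulationSpec, out_prefix) -> dict[str, Path]:
    """Simulate and write a complete ped/tped + phenotype + truth bundle."""
    out_prefix = Path(out_prefix)
    g = simulate_genotypes(spec)
    pheno, truth = simulate_phenotype(g, spec)
    ped, tped = write_ped_tped(g, out_prefix)
    pheno_path = out_prefix.with_suffix(".pheno.tsv")
    pheno.to_csv(pheno_path, sep="\t", index=False)
    truth_path = out_prefix.with_suffix(".truth.tsv")
    pd.DataFrame(truth["planted_pairs"]).to_csv(truth_path, sep="\t", index=False)
    return {"ped": ped, "tped": tped, "phenotype": pheno_path, "truth": truth_path}
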