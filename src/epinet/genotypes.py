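"""Genotype containers, PLINK ped/tped text I/O, encodings and QC.

Genotypes are held as a samples x variants dosage matrix counting copies of
the per-variant minor allele (0, 1, 2; ``NaN`` = missing call).  The minor
allele is determined from the observed allele frequencies in the data, so
the dosage orientation is a property of the dataset, not of the input file.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeTable",
    "ENCODING_SCHEMES",
    "read_ped_tped",
    "write_ped_tped",
    "qc_filter",
    "encode",
    "read_phenotype_table",
    "PlinkFormatError",
    "ConsistencyError",
    "EmptyFilterError",
]

#: Genotype class -> numeric value maps.  Classes are counted as copies of
#: the minor allele: 0 = homozygous major, 1 = heterozygous, 2 = homozygous
#: minor.  ``minor_reversed_j`` is a pair-level scheme (the second locus of a
#: pair has its homozygote labels swapped, i.e. dosage -> 2 - dosage) and is
#: applied during pair fitting, not by :func:`encode`.
ENCODING_SCHEMES = {
    "minor_dominant": {0: 0.0, 1: 1.0, 2: 2.0},
    "gradient": {0: 1.0, 1: 1.5, 2: 2.0},
}

MISSING_ALLELE = "0"


class PlinkFormatError(ValueError):
    """Malformed ped/tped content (reported with the offending line number)."""


class ConsistencyError(ValueError):
    """ped and tped files disagree on sample or variant counts."""


class EmptyFilterError(ValueError):
    """A filter removed every variant."""


def _natural_chrom_key(chrom: str):
    # numeric chromosomes sort numerically, then X/Y/MT etc. lexicographically
    return (0, int(chrom), "") if chrom.isdigit() else (1, 0, chrom)


@dataclass
class GenotypeTable:
    """Samples x variants dosage matrix with per-variant metadata.

    Attributes
    ----------
    variants : pandas.DataFrame
        One row per variant with columns ``id``, ``chrom``, ``pos``,
        ``allele_minor``, ``allele_major``, ``maf``, ``call_rate``.
    samples : list of str
        Sample identifiers, in matrix row order.
    dosage : ndarray of shape (n_samples, n_variants)
        Minor-allele dosage (0/1/2 raw, or scheme values after
        :func:`encode`); ``NaN`` marks missing calls.
    encoding : str or None
        Name of the scheme applied by :func:`encode`, ``None`` for raw.
    """

    variants: pd.DataFrame
    samples: list[str]
    dosage: np.ndarray
    encoding: str | None = None
    sample_info: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def __post_init__(self) -> None:
        self.variants = self.variants.reset_index(drop=True)
        if self.dosage.shape != (len(self.samples), len(self.variants)):
            raise ConsistencyError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )

    def take_variants(self, idx: Sequence[int]) -> "GenotypeTable":
        """Subset to the given variant positions (order preserved as given)."""
        idx = np.asarray(idx, dtype=int)
        return replace(
            self,
            variants=self.variants.iloc[idx].reset_index(drop=True),
            dosage=self.dosage[:, idx],
        )

    def sorted_by_position(self) -> "GenotypeTable":
        order = sorted(
            range(self.n_variants),
            key=lambda k: (
                _natural_chrom_key(str(self.variants["chrom"].iloc[k])),
                int(self.variants["pos"].iloc[k]),
            ),
        )
        return self.take_variants(order)


def _variant_stats(dosage_col: np.ndarray) -> tuple[float, float]:
    """(maf, call_rate) from a raw 0/1/2 dosage column."""
    n = dosage_col.size
    obs = dosage_col[np.isfinite(dosage_col)]
    call_rate = obs.size / n if n else 0.0
    if obs.size == 0:
        return 0.0, call_rate
    freq = obs.sum() / (2 * obs.size)
    return float(min(freq, 1.0 - freq)), float(call_rate)


def read_ped_tped(ped_path, tped_path) -> GenotypeTable:
    """Load a PLINK pedigree/transposed-pedigree pair into a GenotypeTable.

    Genotype calls are taken from the tped (variant-major) file; the ped file
    supplies sample identifiers and its in-file phenotype column, and the two
    files are cross-validated for consistent dimensions.  The minor allele of
    each variant is determined from the observed allele counts; a frequency
    tie (exactly 0.5) is broken toward the lexicographically smaller allele
    so the dosage orientation is deterministic.  Variants are returned sorted
    by (chromosome, position).
    """
    ped_path, tped_path = Path(ped_path), Path(tped_path)

    sample_rows = []
    ped_geno_cols = None
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) < 6 or (len(fields) - 6) % 2:
                raise PlinkFormatError(
                    f"{ped_path.name}:{lineno}: expected 6 leading columns plus "
                    f"allele pairs, got {len(fields)} fields"
                )
            if ped_geno_cols is None:
                ped_geno_cols = len(fields) - 6
            elif len(fields) - 6 != ped_geno_cols:
                raise PlinkFormatError(
                    f"{ped_path.name}:{lineno}: inconsistent number of genotype "
                    f"columns ({len(fields) - 6} vs {ped_geno_cols})"
                )
            sample_rows.append(fields[:6])
    if not sample_rows:
        raise PlinkFormatError(f"{ped_path.name}: no samples found")
    sample_info = pd.DataFrame(
        sample_rows, columns=["fid", "iid", "father", "mother", "sex", "phenotype"]
    )
    samples = list(sample_info["iid"])
    n = len(samples)

    meta_rows = []
    allele_rows = []
    with open(tped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) < 4 or (len(fields) - 4) % 2:
                raise PlinkFormatError(
                    f"{tped_path.name}:{lineno}: expected 4 leading columns plus "
                    f"allele pairs, got {len(fields)} fields"
                )
            if (len(fields) - 4) // 2 != n:
                raise ConsistencyError(
                    f"{tped_path.name}:{lineno}: {(len(fields) - 4) // 2} genotypes "
                    f"but ped file has {n} samples"
                )
            meta_rows.append((fields[1], fields[0], int(fields[3])))
            allele_rows.append(fields[4:])
    m = len(meta_rows)
    if ped_geno_cols != 2 * m:
        raise ConsistencyError(
            f"ped file has {ped_geno_cols // 2} variants worth of genotype "
            f"columns but tped file has {m} variants"
        )

    dosage = np.full((n, m), np.nan)
    minor_alleles, major_alleles = [], []
    for v, alleles in enumerate(allele_rows):
        a1 = np.array(alleles[0::2])
        a2 = np.array(alleles[1::2])
        called = (a1 != MISSING_ALLELE) & (a2 != MISSING_ALLELE)
        observed = np.concatenate([a1[called], a2[called]])
        uniq, counts = np.unique(observed, return_counts=True)
        if uniq.size == 0:
            minor, major = MISSING_ALLELE, MISSING_ALLELE
        elif uniq.size == 1:
            # monomorphic: minor allele undefined, maf will be 0
            minor, major = MISSING_ALLELE, str(uniq[0])
        elif uniq.size == 2:
            if counts[0] < counts[1]:
                minor, major = str(uniq[0]), str(uniq[1])
            elif counts[0] > counts[1]:
                minor, major = str(uniq[1]), str(uniq[0])
            else:  # tie at 0.5: lexicographically smaller allele is minor
                minor, major = str(min(uniq)), str(max(uniq))
        else:
            raise PlinkFormatError(
                f"variant {meta_rows[v][0]}: more than two alleles observed "
                f"({', '.join(uniq)}); only biallelic variants are supported"
            )
        minor_alleles.append(minor)
        major_alleles.append(major)
        if uniq.size:
            dosage[called, v] = (a1[called] == minor).astype(float) + (
                a2[called] == minor
            ).astype(float)

    maf = np.empty(m)
    call_rate = np.empty(m)
    for v in range(m):
        maf[v], call_rate[v] = _variant_stats(dosage[:, v])

    variants = pd.DataFrame(
        {
            "id": [r[0] for r in meta_rows],
            "chrom": [r[1] for r in meta_rows],
            "pos": [r[2] for r in meta_rows],
            "allele_minor": minor_alleles,
            "allele_major": major_alleles,
            "maf": maf,
            "call_rate": call_rate,
        }
    )
    table = GenotypeTable(variants, samples, dosage, sample_info=sample_info)
    return table.sorted_by_position()


def write_ped_tped(g: GenotypeTable, out_prefix) -> tuple[Path, Path]:
    """Write a raw GenotypeTable as ``<prefix>.ped`` and ``<prefix>.tped``.

    Requires the unencoded 0/1/2 dosage representation so genotype classes
    (and hence allele pairs) can be reconstructed; round-trips exactly
    through :func:`read_ped_tped`.
    """
    if g.encoding not in (None, "minor_dominant"):
        raise ValueError(
            f"cannot write a table encoded with '{g.encoding}': genotype "
            "classes are not recoverable; keep the raw table for I/O"
        )
    if g.n_variants == 0:
        raise ValueError("refusing to write a table with no variants")

    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    ped_path = out_prefix.with_suffix(".ped")
    tped_path = out_prefix.with_suffix(".tped")

    # allele pair per genotype class, per variant
    pair_for_class = []
    for _, row in g.variants.iterrows():
        minor, major = row["allele_minor"], row["allele_major"]
        if minor == MISSING_ALLELE:  # monomorphic
            minor = major
        pair_for_class.append(
            {0: f"{major} {major}", 1: f"{major} {minor}", 2: f"{minor} {minor}"}
        )
    missing_pair = f"{MISSING_ALLELE} {MISSING_ALLELE}"

    info = g.sample_info
    with open(ped_path, "w") as fh:
        for s, sid in enumerate(g.samples):
            if info is not None:
                lead = list(info.iloc[s][["fid", "iid", "father", "mother", "sex", "phenotype"]])
            else:
                lead = [sid, sid, "0", "0", "0", "-9"]
            geno = []
            for v in range(g.n_variants):
                d = g.dosage[s, v]
                geno.append(missing_pair if not np.isfinite(d) else pair_for_class[v][int(d)])
            fh.write(" ".join(map(str, lead)) + " " + " ".join(geno) + "\n")

    with open(tped_path, "w") as fh:
        for v, row in g.variants.iterrows():
            geno = []
            for s in range(g.n_samples):
                d = g.dosage[s, v]
                geno.append(missing_pair if not np.isfinite(d) else pair_for_class[v][int(d)])
            fh.write(
                f"{row['chrom']} {row['id']} 0 {row['pos']} " + " ".join(geno) + "\n"
            )
    return ped_path, tped_path


def qc_filter(g: GenotypeTable, min_call_rate: float = 0.0, min_maf: float = 0.0) -> GenotypeTable:
    """Keep variants with call_rate >= min_call_rate and maf >= min_maf."""
    for name, val in (("min_call_rate", min_call_rate), ("min_maf", min_maf)):
        if not 0.0 <= val <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {val}")
    keep = np.flatnonzero(
        (g.variants["call_rate"].to_numpy() >= min_call_rate)
        & (g.variants["maf"].to_numpy() >= min_maf)
    )
    if keep.size == 0:
        raise EmptyFilterError(
            "QC removed every variant; relax min_call_rate/min_maf thresholds"
        )
    return g.take_variants(keep)


def encode(g: GenotypeTable, scheme: str = "minor_dominant") -> GenotypeTable:
    """Map raw genotype classes to the numeric values of an encoding scheme.

    ``minor_dominant`` keeps minor-allele dosage (0, 1, 2); ``gradient`` maps
    the classes to (1, 1.5, 2) so all four alleles of a pair participate in
    the interaction term.  Missing calls stay missing; re-encoding with the
    scheme already applied is a no-op.
    """
    if scheme == "minor_reversed_j":
        raise ValueError(
            "minor_reversed_j is a pair-level orientation (second locus "
            "reversed); it is applied during pair fitting, not by encode()"
        )
    if scheme not in ENCODING_SCHEMES:
        raise ValueError(
            f"unknown encoding scheme {scheme!r}; choose from "
            f"{sorted(ENCODING_SCHEMES)}"
        )
    if g.encoding == scheme:
        return g
    if g.encoding not in (None, "minor_dominant"):
        raise ValueError(f"table already encoded with {g.encoding!r}; re-read raw data")
    value_map = ENCODING_SCHEMES[scheme]
    out = np.full_like(g.dosage, np.nan)
    for cls, val in value_map.items():
        out[g.dosage == cls] = val
    return replace(g, dosage=out, encoding=scheme)


def read_phenotype_table(path) -> pd.DataFrame:
    """Read a delimited phenotype/covariate table (header; first column = sample id)."""
    df = pd.read_csv(path, sep=None, engine="python")
    df = df.rename(columns={df.columns[0]: "sample_id"})
    df["sample_id"] = df["sample_id"].astype(str)
    return df
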