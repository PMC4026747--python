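"""Genotype/trait containers and file readers.

Genotypes are held as an ``n x k`` dosage matrix with entries in {0, 1, 2}
(count of one allele per subject and variant).  File readers re-orient each
variant to the minor allele (dosage counts the less frequent allele), so
that downstream minor-allele frequencies live in [0, 0.5].  Simulated
genotypes keep the coding the generator produced, since the trait model is
defined on that coding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "read_genotypes_tsv",
    "read_genotypes_vcf",
    "read_trait",
]


def _empirical_maf(dosages: np.ndarray) -> np.ndarray:
    """Minor-allele frequency per column: min(p, 1-p) with p = colsum / 2n."""
    p = dosages.mean(axis=0) / 2.0
    return np.minimum(p, 1.0 - p)


@dataclass
class GenotypeMatrix:
    """An ``n x k`` dosage matrix plus per-variant metadata.

    Parameters
    ----------
    dosages
        Integer-valued matrix with entries in {0, 1, 2}; one row per
        subject, one column per variant.
    variant_ids
        Optional variant labels (defaults to ``v1..vk``).
    causal_mask
        Optional boolean mask marking simulated causal variants.
    """

    dosages: np.ndarray
    variant_ids: list[str] = field(default=None)  # type: ignore[assignment]
    causal_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D matrix")
        n, k = self.dosages.shape
        if n < 2 or k < 1:
            raise ValueError("need at least 2 subjects and 1 variant")
        vals = np.unique(self.dosages)
        if not np.all(np.isin(vals, [0.0, 1.0, 2.0])):
            raise ValueError("dosage entries must be 0, 1 or 2")
        if self.variant_ids is None:
            self.variant_ids = [f"v{j + 1}" for j in range(k)]
        if len(self.variant_ids) != k:
            raise ValueError("variant_ids length mismatch")
        if self.causal_mask is not None:
            self.causal_mask = np.asarray(self.causal_mask, dtype=bool)
            if self.causal_mask.shape != (k,):
                raise ValueError("causal_mask length mismatch")

    @property
    def n(self) -> int:
        return self.dosages.shape[0]

    @property
    def k(self) -> int:
        return self.dosages.shape[1]

    @property
    def maf(self) -> np.ndarray:
        return _empirical_maf(self.dosages)

    def polymorphic_mask(self) -> np.ndarray:
        """True for columns that vary across subjects."""
        return self.dosages.std(axis=0) > 0

    def oriented_to_minor_allele(self) -> "GenotypeMatrix":
        """Return a copy with every column counting its minor allele."""
        X = self.dosages.copy()
        flip = X.mean(axis=0) / 2.0 > 0.5
        X[:, flip] = 2.0 - X[:, flip]
        return GenotypeMatrix(X, list(self.variant_ids), self.causal_mask)


def read_genotypes_tsv(path: str, orient: bool = True) -> GenotypeMatrix:
    """Read a tab-delimited dosage matrix (header row = variant ids)."""
    df = pd.read_csv(path, sep="\t")
    geno = GenotypeMatrix(df.to_numpy(dtype=float), list(df.columns))
    return geno.oriented_to_minor_allele() if orient else geno


def read_genotypes_vcf(path: str, orient: bool = True) -> GenotypeMatrix:
    """Read dosages (count of ALT alleles) from a VCF file.

    Requires ``cyvcf2``.  Missing genotypes are counted as homozygous
    reference with a warning; multi-allelic records use any non-reference
    allele as ALT.
    """
    from cyvcf2 import VCF

    ids, cols = [], []
    vcf = VCF(path)
    n_missing = 0
    for var in vcf:
        gt = np.asarray(var.genotypes, dtype=object)
        alleles = np.array([[a if isinstance(a, int) else -1 for a in g[:2]] for g in gt])
        n_missing += int((alleles < 0).sum())
        dose = (alleles > 0).sum(axis=1)
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        cols.append(dose)
    vcf.close()
    if n_missing:
        warnings.warn(f"{n_missing} missing genotype alleles counted as reference")
    if not cols:
        raise ValueError(f"no variant records in {path}")
    geno = GenotypeMatrix(np.column_stack(cols).astype(float), ids)
    return geno.oriented_to_minor_allele() if orient else geno


def read_trait(path: str) -> np.ndarray:
    """Read a quantitative trait, one value per line, aligned to sample order."""
    y = np.loadtxt(path, dtype=float, ndmin=1)
    if y.ndim != 1:
        raise ValueError("trait file must hold one value per line")
    if not np.all(np.isfinite(y)):
        raise ValueError("trait values must be finite")
    return y
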