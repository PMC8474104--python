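"""Core phased-haplotype data containers.

A :class:`HaplotypePanel` stores phased chromosomes as rows of a dense 0/1
matrix; two consecutive rows form one diploid individual. One column may be
flagged as the deletion locus (allele 1 = deletion).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class PanelError(ValueError):
    """Invalid haplotype panel or recombination map."""


@dataclass
class RecombinationMap:
    """Physical positions with local rates and cumulative genetic distance.

    positions_bp are 1-based physical coordinates; cumulative_cM must be
    non-decreasing and aligned with positions.
    """

    positions_bp: np.ndarray
    rate_cM_per_Mb: np.ndarray
    cumulative_cM: np.ndarray

    def __post_init__(self) -> None:
        self.positions_bp = np.asarray(self.positions_bp, dtype=np.int64)
        self.rate_cM_per_Mb = np.asarray(self.rate_cM_per_Mb, dtype=float)
        self.cumulative_cM = np.asarray(self.cumulative_cM, dtype=float)
        n = len(self.positions_bp)
        if len(self.rate_cM_per_Mb) != n or len(self.cumulative_cM) != n:
            raise PanelError("recombination map column lengths differ")
        if np.any(self.rate_cM_per_Mb < 0):
            raise PanelError("negative recombination rate")
        if np.any(np.diff(self.cumulative_cM) < 0):
            raise PanelError("cumulative_cM must be non-decreasing")
        if np.any(np.diff(self.positions_bp) <= 0):
            raise PanelError("map positions must be strictly increasing")

    def cumulative_at(self, positions_bp: np.ndarray) -> np.ndarray:
        """Linear interpolation of cumulative cM at arbitrary positions."""
        return np.interp(np.asarray(positions_bp, dtype=float),
                         self.positions_bp.astype(float), self.cumulative_cM)

    @classmethod
    def uniform(cls, positions_bp, rate_cM_per_Mb: float = 1.0) -> "RecombinationMap":
        pos = np.asarray(positions_bp, dtype=np.int64)
        rates = np.full(len(pos), float(rate_cM_per_Mb))
        cum = np.concatenate([[0.0], np.cumsum(np.diff(pos) * rate_cM_per_Mb / 1e6)])
        return cls(pos, rates, cum)


@dataclass
class HaplotypePanel:
    """Phased 0/1 alleles: rows = chromosomes (2 per individual), cols = variants."""

    alleles: np.ndarray
    variant_ids: list[str]
    positions_bp: np.ndarray
    del_index: int | None = None
    individual_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        self.positions_bp = np.asarray(self.positions_bp, dtype=np.int64)
        if self.alleles.ndim != 2:
            raise PanelError("allele matrix must be 2-D")
        n_chrom, n_var = self.alleles.shape
        if n_chrom % 2 != 0:
            raise PanelError("chromosome count must be even (2 per individual)")
        if len(self.variant_ids) != n_var or len(self.positions_bp) != n_var:
            raise PanelError("variant metadata length mismatch")
        if len(set(self.variant_ids)) != n_var:
            raise PanelError("variant identifiers must be unique")
        if n_var > 1 and np.any(np.diff(self.positions_bp) <= 0):
            raise PanelError("positions must be strictly increasing")
        if not np.isin(self.alleles, (0, 1)).all():
            raise PanelError("alleles must be 0/1")
        if self.del_index is not None and not (0 <= self.del_index < n_var):
            raise PanelError(f"del_index {self.del_index} out of range")
        if not self.individual_ids:
            self.individual_ids = [f"ind{i:05d}" for i in range(n_chrom // 2)]
        if len(self.individual_ids) != n_chrom // 2:
            raise PanelError("individual_ids length must equal half the chromosome count")

    @property
    def n_chromosomes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.alleles.shape[0] // 2

    @property
    def n_variants(self) -> int:
        return self.alleles.shape[1]

    def genotypes(self) -> np.ndarray:
        """Diploid genotype matrix {0,1,2}, individuals x variants."""
        return (self.alleles[0::2, :] + self.alleles[1::2, :]).astype(np.int8)

    def deletion_genotypes(self) -> np.ndarray:
        if self.del_index is None:
            raise PanelError("panel has no flagged deletion locus")
        return self.genotypes()[:, self.del_index]

    def allele_frequency(self, j: int) -> float:
        return float(self.alleles[:, j].mean())

    def subset_variants(self, cols) -> "HaplotypePanel":
        cols = np.asarray(cols)
        del_index = None
        if self.del_index is not None:
            hits = np.nonzero(cols == self.del_index)[0]
            if hits.size:
                del_index = int(hits[0])
        return HaplotypePanel(
            alleles=self.alleles[:, cols],
            variant_ids=[self.variant_ids[c] for c in cols],
            positions_bp=self.positions_bp[cols],
            del_index=del_index,
            individual_ids=list(self.individual_ids),
        )


def chromosome_counts_from_genotypes(n_ref_hom: int, n_het: int, n_alt_hom: int) -> tuple[int, int]:
    """Chromosome-level allele accounting from diploid genotype counts.

    Returns (reference-allele chromosomes, alternate-allele chromosomes):
    ref = 2*n_ref_hom + n_het, alt = n_het + 2*n_alt_hom.
    """
    for v in (n_ref_hom, n_het, n_alt_hom):
        if v < 0:
            raise ValueError("genotype counts must be non-negative")
    return 2 * n_ref_hom + n_het, n_het + 2 * n_alt_hom


def genotype_class_fractions(n_ref_hom: int, n_het: int, n_alt_hom: int) -> np.ndarray:
    """Fractions of the three genotype classes among genotyped individuals."""
    total = n_ref_hom + n_het + n_alt_hom
    if total <= 0:
        raise ValueError("no genotyped individuals")
    return np.array([n_ref_hom, n_het, n_alt_hom], dtype=float) / total
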