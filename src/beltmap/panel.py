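"""Phased SNP panel container.

A :class:`PhasedPanel` holds the two haplotype allele vectors of every animal
on a single chromosome, together with the physical map. Alleles are coded
``0``/``1``; ``-1`` marks a missing call (allowed only before imputation).
Positions are 1-based and strictly increasing; a non-positive position marks
a SNP whose physical location is unknown (such SNPs are removed by QC).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MISSING = -1


@dataclass
class PhasedPanel:
    """Animals x SNPs phased genotype panel on one chromosome.

    Attributes
    ----------
    chrom : str
        Chromosome name (a single chromosome per panel).
    snp_ids : ndarray of str, shape (m,)
    pos : ndarray of int, shape (m,)
        1-based physical positions, strictly increasing among known
        positions; ``<= 0`` means unknown.
    haps : ndarray of int8, shape (n, 2, m)
        Ordered haplotype pair per animal; entries in {0, 1, -1}.
    animal_ids : ndarray of str, shape (n,)
    """

    chrom: str
    snp_ids: np.ndarray
    pos: np.ndarray
    haps: np.ndarray
    animal_ids: np.ndarray
    snp_chroms: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.haps = np.asarray(self.haps, dtype=np.int8)
        self.animal_ids = np.asarray(self.animal_ids, dtype=object)
        if self.haps.ndim != 3 or self.haps.shape[1] != 2:
            raise ValueError("haps must have shape (n_animals, 2, n_snps)")
        n, _, m = self.haps.shape
        if len(self.snp_ids) != m or len(self.pos) != m:
            raise ValueError("snp_ids/pos length does not match haps")
        if len(self.animal_ids) != n:
            raise ValueError("animal_ids length does not match haps")
        if self.snp_chroms is None:
            self.snp_chroms = np.asarray([self.chrom] * m, dtype=object)
        else:
            self.snp_chroms = np.asarray(self.snp_chroms, dtype=object)
        known = self.pos > 0
        if np.any(np.diff(self.pos[known]) <= 0):
            raise ValueError("known positions must be strictly increasing")

    # ------------------------------------------------------------------
    @property
    def n_animals(self) -> int:
        return self.haps.shape[0]

    @property
    def n_snps(self) -> int:
        return self.haps.shape[2]

    def genotypes(self) -> np.ndarray:
        """Dosage matrix (n, m) in {0, 1, 2}; -1 where either allele missing."""
        g = self.haps[:, 0, :].astype(np.int16) + self.haps[:, 1, :]
        g[np.any(self.haps == MISSING, axis=1)] = MISSING
        return g

    def hap_matrix(self) -> np.ndarray:
        """Haplotypes stacked as a (2n, m) matrix; rows 2j, 2j+1 belong to animal j."""
        n, _, m = self.haps.shape
        return self.haps.reshape(n * 2, m)

    def subset_snps(self, mask_or_index) -> "PhasedPanel":
        idx = np.asarray(mask_or_index)
        return PhasedPanel(
            chrom=self.chrom,
            snp_ids=self.snp_ids[idx],
            pos=self.pos[idx],
            haps=self.haps[:, :, idx],
            animal_ids=self.animal_ids,
            snp_chroms=self.snp_chroms[idx],
        )

    def subset_animals(self, mask_or_index) -> "PhasedPanel":
        idx = np.asarray(mask_or_index)
        return PhasedPanel(
            chrom=self.chrom,
            snp_ids=self.snp_ids,
            pos=self.pos,
            haps=self.haps[idx],
            animal_ids=self.animal_ids[idx],
            snp_chroms=self.snp_chroms,
        )

    def has_missing(self) -> bool:
        return bool(np.any(self.haps == MISSING))

    def __eq__(self, other: object) -> bool:  # bit-identity, used for determinism checks
        if not isinstance(other, PhasedPanel):
            return NotImplemented
        return (
            self.chrom == other.chrom
            and np.array_equal(self.snp_ids, other.snp_ids)
            and np.array_equal(self.pos, other.pos)
            and np.array_equal(self.haps, other.haps)
            and np.array_equal(self.animal_ids, other.animal_ids)
        )
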