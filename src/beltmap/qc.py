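"""Genotype quality control and phenotype coding.

SNP filters are applied in a fixed order, so every removed SNP records
exactly one primary reason (the first failing rule):

1. call rate below threshold (default 0.95),
2. trio Mendelian error rate above threshold (default 0.002),
3. unknown physical position,
4. minor allele frequency below threshold (default 0.025, computed on the
   observed alleles of the remaining SNPs),
5. SNP mapped to a chromosome other than the target.

Phasing and imputation are deliberately not reimplemented: the pipeline
consumes externally phased input (or the simulator's truth phase).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import MISSING, PhasedPanel

GROUP_CODE = {"nonbelted": 1.0, "het": 2.0, "likely_hom": 3.0, "ambiguous": 2.5}

REASONS = ("call_rate", "mendel", "position", "maf", "chromosome")


class EmptyPanelError(RuntimeError):
    """Raised when every SNP fails QC."""


@dataclass
class QcThresholds:
    call_rate: float = 0.95
    mendel: float = 0.002
    maf: float = 0.025

    def __post_init__(self) -> None:
        for name in ("call_rate", "mendel", "maf"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} threshold must be in (0, 1)")


@dataclass
class QcReport:
    """Per-SNP QC metrics and pass/fail bookkeeping."""

    table: pd.DataFrame  # snp_id, pos, call_rate, maf, mendel_rate, passed, reason

    @property
    def n_pass(self) -> int:
        return int(self.table["passed"].sum())

    @property
    def n_fail(self) -> int:
        return int((~self.table["passed"]).sum())

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, na_rep="NA")


def _possible_offspring(gs: int, gd: int) -> set:
    allele = {0: {0}, 1: {0, 1}, 2: {1}}
    return {a + b for a in allele[gs] for b in allele[gd]}


def mendelian_error_rate(genotypes: np.ndarray, trios) -> float | None:
    """Fraction of fully genotyped trios with an impossible offspring genotype.

    Parameters
    ----------
    genotypes : (n_animals,) int array of dosages at one SNP, -1 = missing.
    trios : iterable of (offspring, sire, dam) animal indices.

    Returns None when no trio is fully genotyped (rate undefined; the SNP
    then passes the Mendelian rule vacuously).
    """
    g = np.asarray(genotypes)
    complete = 0
    errors = 0
    for child, sire, dam in trios:
        gc, gs, gd = int(g[child]), int(g[sire]), int(g[dam])
        if MISSING in (gc, gs, gd):
            continue
        complete += 1
        if gc not in _possible_offspring(gs, gd):
            errors += 1
    if complete == 0:
        return None
    return errors / complete


def filter_snps(
    panel: PhasedPanel,
    trios=(),
    thresholds: QcThresholds | None = None,
    target_chrom: str | None = None,
):
    """Apply the SNP filters in their fixed order; return (panel, QcReport).

    Raises EmptyPanelError if nothing survives.
    """
    thr = thresholds or QcThresholds()
    target = target_chrom if target_chrom is not None else panel.chrom
    g = panel.genotypes()
    n, m = g.shape

    called = g != MISSING
    call_rate = called.mean(axis=0)
    with np.errstate(invalid="ignore"):
        alt = np.where(called, g, 0).sum(axis=0).astype(float)
        denom = 2.0 * called.sum(axis=0)
        freq = np.divide(alt, denom, out=np.full(m, np.nan), where=denom > 0)
    maf = np.minimum(freq, 1.0 - freq)

    mendel = np.full(m, np.nan)
    if len(trios) > 0:
        for i in range(m):
            r = mendelian_error_rate(g[:, i], trios)
            mendel[i] = np.nan if r is None else r

    reason = np.full(m, "", dtype=object)
    for i in range(m):
        if call_rate[i] < thr.call_rate:
            reason[i] = "call_rate"
        elif not np.isnan(mendel[i]) and mendel[i] > thr.mendel:
            reason[i] = "mendel"
        elif panel.pos[i] <= 0:
            reason[i] = "position"
        elif np.isnan(maf[i]) or maf[i] < thr.maf:
            reason[i] = "maf"
        elif panel.snp_chroms[i] != target:
            reason[i] = "chromosome"
    passed = reason == ""

    report = QcReport(
        pd.DataFrame(
            {
                "snp_id": panel.snp_ids,
                "pos": panel.pos,
                "call_rate": call_rate,
                "maf": maf,
                "mendel_rate": mendel,
                "passed": passed,
                "reason": reason,
            }
        )
    )
    if not passed.any():
        raise EmptyPanelError("empty panel: all SNPs removed by QC")
    return panel.subset_snps(passed), report


def encode_phenotypes(groups, animal_ids=None, breeds=None) -> pd.DataFrame:
    """Map phenotype groups to the numeric codes used as the model response.

    nonbelted -> 1, het -> 2, likely_hom -> 3, ambiguous -> 2.5.
    """
    groups = list(groups)
    for gname in groups:
        if gname not in GROUP_CODE:
            raise ValueError(f"unknown phenotype group: {gname!r}")
    out = pd.DataFrame({"group": groups, "code": [GROUP_CODE[gname] for gname in groups]})
    if animal_ids is not None:
        out.insert(0, "animal_id", list(animal_ids))
    if breeds is not None:
        out.insert(1, "breed", list(breeds))
    return out
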