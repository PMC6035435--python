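"""Readers and writers for the plain-text interchange formats.

Phased VCF (``GT`` with the ``|`` separator) is the primary genotype format;
PLINK-style ``.ped``/``.map`` is accepted with the written allele order taken
as the phase. Depth tracks are BEDGRAPH (0-based half-open), split reads a
TSV sketch, qPCR results a CSV.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .panel import MISSING, PhasedPanel


class UnphasedGenotypeError(ValueError):
    """Raised when a VCF genotype uses '/' instead of '|'."""


# ----------------------------------------------------------------------
# phased VCF
def write_phased_vcf(panel: PhasedPanel, path) -> None:
    code = {0: "0", 1: "1", MISSING: "."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={panel.chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(map(str, panel.animal_ids))
            + "\n"
        )
        for i in range(panel.n_snps):
            gts = "\t".join(
                f"{code[int(panel.haps[j, 0, i])]}|{code[int(panel.haps[j, 1, i])]}"
                for j in range(panel.n_animals)
            )
            fh.write(
                f"{panel.snp_chroms[i]}\t{panel.pos[i]}\t{panel.snp_ids[i]}\tA\tG\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_phased_vcf(path) -> PhasedPanel:
    """Read a single-chromosome phased VCF into a PhasedPanel.

    Unphased genotypes are rejected: upstream phasing (e.g. BEAGLE) is an
    explicit external dependency of the pipeline.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    animal_ids = np.array(vcf.samples, dtype=object)
    snp_ids, pos, chroms, rows = [], [], [], []
    for var in vcf:
        gts = var.genotype.array()  # (n, 3): allele0, allele1, phased flag
        if np.any((gts[:, 2] == 0) & (gts[:, 0] >= 0)):
            raise UnphasedGenotypeError(
                f"unphased genotype at {var.CHROM}:{var.POS}; phased input required"
            )
        snp_ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        pos.append(var.POS)
        chroms.append(var.CHROM)
        rows.append(np.where(gts[:, :2] < 0, MISSING, gts[:, :2]).astype(np.int8))
    vcf.close()
    if not rows:
        raise ValueError("no variants in VCF")
    haps = np.stack(rows, axis=2)  # (n, 2, m)
    return PhasedPanel(chroms[0], snp_ids, pos, haps, animal_ids, snp_chroms=chroms)


# ----------------------------------------------------------------------
# PLINK .ped/.map (allele order in the .ped taken as written phase)
def write_plink(panel: PhasedPanel, prefix) -> None:
    with open(f"{prefix}.map", "w") as fh:
        for i in range(panel.n_snps):
            fh.write(f"{panel.snp_chroms[i]}\t{panel.snp_ids[i]}\t0\t{panel.pos[i]}\n")
    code = {0: "1", 1: "2", MISSING: "0"}
    with open(f"{prefix}.ped", "w") as fh:
        for j in range(panel.n_animals):
            alleles = " ".join(
                f"{code[int(panel.haps[j, 0, i])]} {code[int(panel.haps[j, 1, i])]}"
                for i in range(panel.n_snps)
            )
            fh.write(f"FAM {panel.animal_ids[j]} 0 0 0 -9 {alleles}\n")


def read_plink(prefix) -> PhasedPanel:
    mp = pd.read_csv(f"{prefix}.map", sep=r"\s+", header=None, names=["chrom", "snp_id", "cm", "pos"])
    decode = {"1": 0, "2": 1, "0": MISSING}
    animal_ids, hap_rows = [], []
    with open(f"{prefix}.ped") as fh:
        for line in fh:
            parts = line.split()
            animal_ids.append(parts[1])
            alleles = parts[6:]
            a0 = np.array([decode[a] for a in alleles[0::2]], dtype=np.int8)
            a1 = np.array([decode[a] for a in alleles[1::2]], dtype=np.int8)
            hap_rows.append(np.stack([a0, a1]))
    haps = np.stack(hap_rows)  # (n, 2, m)
    return PhasedPanel(
        str(mp["chrom"].iloc[0]),
        mp["snp_id"].to_numpy(dtype=object),
        mp["pos"].to_numpy(),
        haps,
        np.array(animal_ids, dtype=object),
        snp_chroms=mp["chrom"].astype(str).to_numpy(dtype=object),
    )


# ----------------------------------------------------------------------
# phenotype / depth / split reads / qPCR
def write_phenotypes(pheno: pd.DataFrame, path) -> None:
    pheno.to_csv(path, sep="\t", index=False)


def read_phenotypes(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"animal_id": str, "breed": str, "group": str})


def write_bedgraph(chrom: str, start_1based: int, depth: np.ndarray, path) -> None:
    """Run-length-compressed BEDGRAPH (0-based half-open intervals)."""
    depth = np.asarray(depth)
    change = np.flatnonzero(np.diff(depth)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(depth)]])
    off = start_1based - 1
    with open(path, "w") as fh:
        fh.write('track type=bedGraph name="depth"\n')
        for s, e in zip(starts, ends):
            fh.write(f"{chrom}\t{off + s}\t{off + e}\t{int(depth[s])}\n")


def read_bedgraph(path):
    """Return (chrom, start_1based, per-base depth array)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith(("track", "#")) or not line.strip():
                continue
            chrom, s, e, v = line.split()
            rows.append((chrom, int(s), int(e), float(v)))
    if not rows:
        raise ValueError("empty bedgraph")
    chrom = rows[0][0]
    start0, end0 = rows[0][1], max(r[2] for r in rows)
    depth = np.zeros(end0 - start0, dtype=float)
    for _, s, e, v in rows:
        depth[s - start0 : e - start0] = v
    return chrom, start0 + 1, depth


def write_split_reads(split_reads: pd.DataFrame, path) -> None:
    split_reads.to_csv(path, sep="\t", index=False)


def read_split_reads(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"clip_seq": str, "clip_side": str})


def write_qpcr(qpcr: pd.DataFrame, path) -> None:
    qpcr.to_csv(path, index=False)


def read_qpcr(path) -> pd.DataFrame:
    return pd.read_csv(path)
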