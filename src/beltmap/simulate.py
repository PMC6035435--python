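"""Synthetic cohort generator.

Generates every input the mapping and copy-number pipeline consumes, with the
statistical structure the analysis assumes:

* a multi-breed diploid cohort whose haplotypes are mosaics of breed-specific
  founder haplotypes (Li-Stephens-style copying), so linkage disequilibrium
  decays with physical distance;
* a dominant "belt" allele planted as a haplotype tag that travels with a
  shared ancestral core haplotype introgressed into every belted breed — the
  causal allele itself is invisible to the SNP panel, as in reality, and is
  tagged only through LD with flanking markers;
* four phenotype groups (non-belted / heterozygous / likely homozygous /
  ambiguous) including a controllable fraction of heterozygotes deliberately
  mislabelled "likely homozygous";
* missing genotypes, and Mendelian-inconsistent offspring genotypes planted
  in a fixed trio subset, for exercising QC;
* Poisson per-base read depth scaled by candidate-segment copy number, with
  junction-spanning split reads carrying the soft-clipped partner sequence;
* qPCR Cq values generated from a log-linear standard curve with Gaussian
  noise.

Copy-number convention: a non-carrier diplotype holds 2 copies of the
candidate segment (one per chromosome); a carrier haplotype holds
``belt_copies`` tandem copies, so a heterozygous carrier has
``belt_copies + 1`` and a homozygous carrier ``2 * belt_copies`` copies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import MISSING, PhasedPanel

#: Post-exclusion study cohort template: (breed, n_animals, breed_is_belted).
#: Mirrors the published composition after removal of atypical phenotypes:
#: 37 Belted Galloway, 29 plain Galloway, 26 Dutch Belted, 18 Gurtenvieh
#: (incl. crosses) = 110 animals, of which the plain Galloway contribute no
#: belt haplotypes.
BREED_TEMPLATE = (
    ("BGA", 37, True),
    ("GAL", 29, False),
    ("DBE", 26, True),
    ("GUV", 18, True),
)

GROUPS = ("nonbelted", "het", "likely_hom", "ambiguous")


def study_cohort_composition() -> pd.DataFrame:
    """The published cohort bookkeeping, before exclusions.

    Returns one row per sampling stratum with the number of animals, how
    many of them are belted, and how many were excluded for an atypical
    phenotype. Applying the exclusions reproduces the mapping cohort of
    110 animals (78 belted, 32 plain-coloured).
    """
    rows = [
        # stratum, sampled, belted, excluded (excluded animals are belted)
        ("Belted Galloway", 43, 43, 6),
        ("Black/Red Galloway", 29, 0, 0),
        ("Dutch Belted", 26, 26, 0),
        ("Gurtenvieh", 19, 19, 5),
        ("non-belted Gurtenvieh offspring", 2, 0, 0),
        ("Gurtenvieh x Pinzgauer siblings", 2, 1, 0),
    ]
    return pd.DataFrame(rows, columns=["stratum", "sampled", "belted", "excluded"])


def apply_cohort_exclusions(composition: pd.DataFrame) -> dict:
    """Apply the atypical-phenotype exclusions to a cohort composition table.

    Excluded animals are belted (exclusion was for atypical *belt*
    phenotype), so both totals shrink accordingly.
    """
    total = int((composition["sampled"] - composition["excluded"]).sum())
    belted = int((composition["belted"] - composition["excluded"]).sum())
    return {"total": total, "belted": belted, "nonbelted": total - belted}


# ----------------------------------------------------------------------
@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic cohort.

    Rates are probabilities per SNP (or per genotype) in [0, 1]. A fixed
    ``seed`` makes every output bit-identical across runs.
    """

    n_snps: int = 2000
    n_founders: int = 10
    n_animals: int = 110
    chrom_length_bp: int = 121_000_000
    copy_switch_rate: float = 0.04
    allele_flip_rate: float = 0.002
    belt_snp_index: int = 1300
    belt_copies: int = 4
    missing_rate: float = 0.01
    mendel_error_rate: float = 0.001
    likelyhom_misclass_rate: float = 0.10
    seed: int = 0
    # cohort-structure knobs (defaulted; not part of the minimal surface)
    chrom: str = "3"
    n_belt_founders: int = 6
    belt_core_snps: int = 60
    belt_segment_decay: float = 0.02  # per-SNP end probability of the carrier segment
    ambiguous_rate: float = 0.05
    trio_fraction: float = 0.10
    fst: float = 0.05
    breeds: tuple = BREED_TEMPLATE

    def __post_init__(self) -> None:
        for name in (
            "copy_switch_rate",
            "allele_flip_rate",
            "missing_rate",
            "mendel_error_rate",
            "likelyhom_misclass_rate",
            "ambiguous_rate",
            "trio_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_animals < 2:
            raise ValueError("n_animals must be >= 2")
        if self.n_snps < 41:
            raise ValueError("n_snps must be >= 41 (a 40-SNP window must fit)")
        if not 0 <= self.belt_snp_index < self.n_snps:
            raise ValueError("belt_snp_index out of range")
        if self.belt_copies < 1:
            raise ValueError("belt_copies must be >= 1")
        if self.n_founders < 1:
            raise ValueError("n_founders must be >= 1")
        if self.n_belt_founders > self.n_founders:
            raise ValueError("n_belt_founders cannot exceed n_founders")


@dataclass
class Truth:
    """Ground truth of a simulated cohort (one record per animal in `table`)."""

    table: pd.DataFrame  # animal_id, breed, true_copies, belted_true, group, code
    hap_carrier: np.ndarray  # (n, 2) bool: haplotype carries the belt allele
    true_haps: np.ndarray  # (n, 2, m) int8, complete and error-free phase
    trios: list  # (offspring, sire, dam) animal indices
    planted_mendel: list  # (trio_index, snp_index) of planted inconsistencies
    belt_snp_index: int
    belt_bp: int

    def copies_per_diplotype(self, belt_copies: int) -> np.ndarray:
        """Candidate-segment copies per animal: 2, belt_copies+1 or 2*belt_copies."""
        carriers = self.hap_carrier.sum(axis=1)
        return 2 + carriers * (belt_copies - 1)


GROUP_CODE = {"nonbelted": 1.0, "het": 2.0, "likely_hom": 3.0, "ambiguous": 2.5}


def _breed_counts(cfg: SimConfig) -> list:
    """Scale the breed template to cfg.n_animals, preserving proportions."""
    total = sum(c for _, c, _ in cfg.breeds)
    raw = [(name, cfg.n_animals * c / total, belted) for name, c, belted in cfg.breeds]
    counts = [max(1, int(round(x))) for _, x, _ in raw]
    # fix rounding so the total is exact
    while sum(counts) > cfg.n_animals:
        counts[int(np.argmax(counts))] -= 1
    while sum(counts) < cfg.n_animals:
        counts[int(np.argmin(counts))] += 1
    return [(name, k, belted) for (name, _, belted), k in zip(raw, counts)]


def simulate_panel(cfg: SimConfig):
    """Simulate the cohort: phased panel, phenotype table and truth records.

    Returns
    -------
    panel : PhasedPanel
        Observed panel (genotyping error, missingness and planted Mendelian
        inconsistencies applied) with the true phase order.
    phenotype : pandas.DataFrame
        Columns ``animal_id, breed, group, code`` (group labels as recorded,
        i.e. after deliberate misclassification).
    truth : Truth
    """
    rng = np.random.default_rng(cfg.seed)
    m = cfg.n_snps

    pos = np.sort(rng.choice(np.arange(1, cfg.chrom_length_bp + 1), size=m, replace=False))
    snp_ids = np.array([f"snp{i:05d}" for i in range(m)], dtype=object)

    # ancestral allele frequencies and the shared introgressed belt haplotype
    p_anc = rng.uniform(0.1, 0.9, size=m)
    belt_hap = (rng.random(m) < p_anc).astype(np.int8)
    half = cfg.belt_core_snps // 2
    core_lo = max(0, cfg.belt_snp_index - half)
    core_hi = min(m, cfg.belt_snp_index + half + 1)

    breeds = _breed_counts(cfg)
    founders = {}
    founder_tag = {}
    for name, _, breed_belted in breeds:
        if cfg.fst > 0 and cfg.fst < 1:
            a = p_anc * (1 - cfg.fst) / cfg.fst
            b = (1 - p_anc) * (1 - cfg.fst) / cfg.fst
            p_breed = rng.beta(a, b)
        else:
            p_breed = p_anc
        fh = (rng.random((cfg.n_founders, m)) < p_breed[None, :]).astype(np.int8)
        tag = np.zeros(cfg.n_founders, dtype=bool)
        if breed_belted and cfg.n_belt_founders > 0:
            tagged = rng.choice(cfg.n_founders, size=cfg.n_belt_founders, replace=False)
            tag[tagged] = True
            # introgressed core: tagged founders carry the shared ancestral
            # belt haplotype around the (SNP-invisible) causal site
            fh[np.ix_(tagged, np.arange(core_lo, core_hi))] = belt_hap[core_lo:core_hi]
        founders[name] = fh
        founder_tag[name] = tag

    animal_breed = np.concatenate([[name] * k for name, k, _ in breeds])
    n = cfg.n_animals
    animal_ids = np.array([f"{animal_breed[j]}{j:03d}" for j in range(n)], dtype=object)

    # trio layout: the last trio_fraction of each breed block are offspring
    # of two earlier animals of the same breed (fixed per seed)
    trios = []
    offspring = np.zeros(n, dtype=bool)
    start = 0
    for name, k, _ in breeds:
        n_off = int(np.floor(k * cfg.trio_fraction))
        if k - n_off >= 2:
            for j in range(start + k - n_off, start + k):
                sire, dam = rng.choice(np.arange(start, start + k - n_off), size=2, replace=False)
                trios.append((j, int(sire), int(dam)))
                offspring[j] = True
        start += k

    true_haps = np.zeros((n, 2, m), dtype=np.int8)
    hap_carrier = np.zeros((n, 2), dtype=bool)

    for j in range(n):
        if offspring[j]:
            continue
        fh = founders[animal_breed[j]]
        tag = founder_tag[animal_breed[j]]
        for h in range(2):
            src = _mosaic_sources(rng, cfg.n_founders, m, cfg.copy_switch_rate)
            alleles = fh[src, np.arange(m)].copy()
            flips = rng.random(m) < cfg.allele_flip_rate
            alleles[flips] ^= 1
            carrier = bool(tag[src[cfg.belt_snp_index]])
            if carrier:
                # a carrier haplotype holds the introgressed ancestral
                # segment intact around the causal site; its extent is
                # geometric per side (recent IBD, longer than background LD)
                lext = int(rng.geometric(cfg.belt_segment_decay))
                rext = int(rng.geometric(cfg.belt_segment_decay))
                lo = max(core_lo, cfg.belt_snp_index - lext)
                hi = min(core_hi, cfg.belt_snp_index + rext + 1)
                alleles[lo:hi] = belt_hap[lo:hi]
            true_haps[j, h] = alleles
            hap_carrier[j, h] = carrier

    recomb = min(1.0, 1.5 / m)  # ~1.5 expected crossovers per gamete
    for child, sire, dam in trios:
        for h, parent in ((0, sire), (1, dam)):
            src = _mosaic_sources(rng, 2, m, recomb)
            true_haps[child, h] = true_haps[parent, src, np.arange(m)]
            hap_carrier[child, h] = hap_carrier[parent, src[cfg.belt_snp_index]]

    true_copies = hap_carrier.sum(axis=1)
    belted_true = true_copies >= 1

    # phenotype groups: truth first, then deliberate misclassification
    group = np.empty(n, dtype=object)
    for j in range(n):
        if not belted_true[j]:
            group[j] = "nonbelted"
        elif rng.random() < cfg.ambiguous_rate:
            group[j] = "ambiguous"
        elif true_copies[j] == 2:
            group[j] = "likely_hom"
        else:
            group[j] = "likely_hom" if rng.random() < cfg.likelyhom_misclass_rate else "het"

    # observed panel: start from truth, plant Mendelian errors, then missingness
    haps = true_haps.copy()
    planted = []
    for t, (child, sire, dam) in enumerate(trios):
        hits = np.flatnonzero(rng.random(m) < cfg.mendel_error_rate)
        for i in hits:
            gs = int(true_haps[sire, :, i].sum())
            gd = int(true_haps[dam, :, i].sum())
            bad = _impossible_genotype(gs, gd)
            if bad is None:
                continue
            haps[child, 0, i] = 1 if bad == 2 else 0
            haps[child, 1, i] = 1 if bad >= 1 else 0
            planted.append((t, int(i)))

    miss = rng.random((n, m)) < cfg.missing_rate
    haps[np.repeat(miss[:, None, :], 2, axis=1)] = MISSING

    panel = PhasedPanel(cfg.chrom, snp_ids, pos, haps, animal_ids)
    code = np.array([GROUP_CODE[g] for g in group])
    phenotype = pd.DataFrame(
        {"animal_id": animal_ids, "breed": animal_breed, "group": group, "code": code}
    )
    truth = Truth(
        table=pd.DataFrame(
            {
                "animal_id": animal_ids,
                "breed": animal_breed,
                "true_copies": true_copies,
                "belted_true": belted_true,
                "group": group,
            }
        ),
        hap_carrier=hap_carrier,
        true_haps=true_haps,
        trios=trios,
        planted_mendel=planted,
        belt_snp_index=cfg.belt_snp_index,
        belt_bp=int(pos[cfg.belt_snp_index]),
    )
    return panel, phenotype, truth


def _mosaic_sources(rng: np.random.Generator, n_sources: int, m: int, switch: float) -> np.ndarray:
    """Per-SNP source index of a mosaic copying process over n_sources templates."""
    first = rng.integers(n_sources)
    switches = rng.random(m - 1) < switch
    new = rng.integers(n_sources, size=m - 1)
    switch_pos = np.flatnonzero(switches) + 1
    starts = np.concatenate([[0], switch_pos])
    vals = np.concatenate([[first], new[switch_pos - 1]])
    lengths = np.diff(np.concatenate([starts, [m]]))
    return np.repeat(vals, lengths)


def _impossible_genotype(gs: int, gd: int):
    """A child genotype impossible under the parents, or None if all 3 are possible."""
    allele = {0: {0}, 1: {0, 1}, 2: {1}}
    possible = {a + b for a in allele[gs] for b in allele[gd]}
    for g in (0, 2, 1):
        if g not in possible:
            return g
    return None


# ----------------------------------------------------------------------
# read-depth and split-read simulation
@dataclass
class DepthSim:
    """Per-animal depth tracks plus split reads over region +/- flanks."""

    chrom: str
    track_start: int  # 1-based position of depth[aid][0]
    depth: dict  # animal_id -> int array over [track_start, track_end]
    split_reads: pd.DataFrame  # animal_id, read_id, mapped_start, mapped_end, clip_side, clip_seq
    ref_seq: str  # reference sequence over the track span
    region: tuple  # (start, end) 1-based inclusive candidate segment


def simulate_depth(
    truth: Truth,
    region: tuple,
    flanks: tuple,
    mean_cov: float = 30.0,
    read_len: int = 100,
    seed: int = 0,
    belt_copies: int = 4,
    junction_cov: float | None = None,
    chrom_length_bp: int | None = None,
    chrom: str = "3",
) -> DepthSim:
    """Simulate per-base depth and junction-spanning split reads.

    Depth is Poisson(mean_cov * copies / 2) inside the candidate ``region``
    and Poisson(mean_cov) outside, per animal. For each carrier haplotype a
    head-to-tail tandem of ``belt_copies`` units has ``belt_copies - 1``
    internal junctions; the expected number of junction-spanning reads is
    ``junction_cov`` per junction (default ``mean_cov / 2``, i.e. the
    per-haplotype coverage). Each split read ends at one array boundary and
    its soft-clipped tail continues with the sequence found at the other
    boundary.
    """
    rstart, rend = int(region[0]), int(region[1])
    if rstart >= rend or rstart < 1:
        raise ValueError("invalid candidate region")
    if chrom_length_bp is not None and rend > chrom_length_bp:
        raise ValueError("candidate region outside chromosome")
    spans = [(rstart, rend)] + [(int(a), int(b)) for a, b in flanks]
    track_start = min(s for s, _ in spans)
    track_end = max(e for _, e in spans)
    if track_start < 1:
        raise ValueError("flank outside chromosome")
    if chrom_length_bp is not None and track_end > chrom_length_bp:
        raise ValueError("flank outside chromosome")
    L = track_end - track_start + 1

    rng = np.random.default_rng(seed)
    ref_seq = "".join(rng.choice(list("ACGT"), size=L))
    if junction_cov is None:
        junction_cov = mean_cov / 2.0

    copies = truth.copies_per_diplotype(belt_copies)
    in_region = np.zeros(L, dtype=bool)
    in_region[rstart - track_start : rend - track_start + 1] = True

    depth = {}
    records = []
    read_no = 0
    for j, aid in enumerate(truth.table["animal_id"]):
        lam = np.where(in_region, mean_cov * copies[j] / 2.0, mean_cov)
        depth[aid] = rng.poisson(lam)
        n_carrier = int(truth.hap_carrier[j].sum())
        n_junctions = n_carrier * (belt_copies - 1)
        if n_junctions == 0:
            continue
        n_reads = rng.poisson(junction_cov * n_junctions)
        for _ in range(n_reads):
            read_no += 1
            aligned = int(rng.integers(30, max(31, read_len - 20)))
            clip_len = read_len - aligned
            if rng.random() < 0.5:
                # read runs off the right array boundary; clip continues at
                # the left boundary of the unit
                mend = rend
                mstart = rend - aligned + 1
                clip = ref_seq[rstart - track_start : rstart - track_start + clip_len]
                side = "right"
            else:
                mstart = rstart
                mend = rstart + aligned - 1
                clip = ref_seq[rend - track_start - clip_len + 1 : rend - track_start + 1]
                side = "left"
            records.append((aid, f"read{read_no:05d}", mstart, mend, side, clip))

    split_reads = pd.DataFrame(
        records,
        columns=["animal_id", "read_id", "mapped_start", "mapped_end", "clip_side", "clip_seq"],
    )
    return DepthSim(
        chrom=chrom,
        track_start=track_start,
        depth=depth,
        split_reads=split_reads,
        ref_seq=ref_seq,
        region=(rstart, rend),
    )


# ----------------------------------------------------------------------
# qPCR simulation
DEFAULT_CURVE = (30.0, -3.321928)  # intercept (Cq), slope (Cq per log10 quantity)


def simulate_qpcr(
    copies: int,
    curve: tuple = DEFAULT_CURVE,
    noise_sd: float = 0.0,
    seed: int = 0,
    dilutions: tuple = (1.0, 0.1, 0.01, 0.001),
    sample: str = "S1",
    target: str = "belt2",
    reference: str = "lpo",
) -> pd.DataFrame:
    """Simulate Cq values for one sample plus a standard-curve dilution series.

    ``Cq = a + b*log10(quantity) + N(0, noise_sd)``. The dilution series uses
    a non-carrier reference DNA (2 copies of both amplicon sites), so the
    standard quantity at dilution d is ``2*d`` for both amplicons. The test
    sample has ``copies`` copies at the target amplicon and always 2 at the
    reference amplicon.
    """
    a, b = curve
    rng = np.random.default_rng(seed)
    rows = []
    for amp in (target, reference):
        for d in dilutions:
            q = 2.0 * d
            cq = a + b * np.log10(q) + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
            rows.append(("std", amp, cq, d))
    for amp, q in ((target, float(copies)), (reference, 2.0)):
        cq = a + b * np.log10(q) + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
        rows.append((sample, amp, cq, np.nan))
    return pd.DataFrame(rows, columns=["sample", "amplicon", "Cq", "dilution"])
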