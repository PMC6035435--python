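"""Inner candidate haplotype (IC-Hap) search inside the extended interval.

An IC-Hap is a short allele string that is carried by at least one haplotype
of *every* belted animal (dominant carrier logic) and by *no* haplotype of
any non-belted animal. The search enumerates every contiguous sub-window of
the interval with a configurable SNP length, tests each observed allele
string against the presence/absence criterion, and merges overlapping
qualifying windows whose alleles agree on the shared SNPs (and whose merged
string still qualifies) into maximal blocks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import PhasedPanel

BELTED_GROUPS = {"het", "likely_hom", "ambiguous"}


@dataclass
class CandidateHaplotype:
    start_snp: int  # index into the searched panel
    end_snp: int  # inclusive
    start_bp: int
    end_bp: int
    n_snps: int
    alleles: str  # e.g. "010110"
    carrier_breeds: tuple
    carrier_counts: dict  # group -> number of belted carriers


def _carrier_mask(hap_block: np.ndarray, alleles: np.ndarray) -> np.ndarray:
    """Per-animal: does at least one haplotype match the allele string."""
    match = np.all(hap_block == alleles[None, None, :], axis=2)  # (n, 2)
    return match.any(axis=1)


def _qualifies(hap_block, alleles, belted, nonbelted) -> bool:
    carrier = _carrier_mask(hap_block, alleles)
    return bool(carrier[belted].all() and not carrier[nonbelted].any())


def find_ic_haps(
    panel: PhasedPanel,
    phenotype: pd.DataFrame,
    len_min: int = 4,
    len_max: int = 12,
    include_ambiguous: bool = True,
) -> list:
    """Enumerate IC-Haps in the (already restricted) panel.

    ``phenotype`` must carry ``animal_id`` and ``group`` columns aligned with
    the panel's animals. Ambiguous-genotype belted animals count as belted
    (must carry) by default; with ``include_ambiguous=False`` they are
    ignored by both criteria.

    Returns CandidateHaplotype blocks sorted by start bp; an empty list when
    nothing qualifies.
    """
    groups = phenotype.set_index("animal_id").loc[list(panel.animal_ids), "group"].to_numpy()
    belted_set = BELTED_GROUPS if include_ambiguous else BELTED_GROUPS - {"ambiguous"}
    belted = np.array([g in belted_set for g in groups])
    nonbelted = groups == "nonbelted"
    if not belted.any() or not nonbelted.any():
        raise ValueError("need at least one belted and one non-belted animal")

    m = panel.n_snps
    H = panel.haps  # (n, 2, m)
    candidates = []  # (start, end_inclusive, allele tuple)
    for length in range(len_min, min(len_max, m) + 1):
        for s in range(0, m - length + 1):
            block = H[:, :, s : s + length]
            # distinct complete allele strings carried by belted animals
            strings = {
                tuple(block[j, h])
                for j in np.flatnonzero(belted)
                for h in range(2)
                if np.all(block[j, h] >= 0)
            }
            for alleles in strings:
                arr = np.asarray(alleles, dtype=H.dtype)
                if _qualifies(block, arr, belted, nonbelted):
                    candidates.append((s, s + length - 1, alleles))

    merged = _merge_candidates(candidates, H, belted, nonbelted)

    out = []
    for s, e, alleles in sorted(merged):
        arr = np.asarray(alleles, dtype=H.dtype)
        carrier = _carrier_mask(H[:, :, s : e + 1], arr)
        breeds = ()
        if "breed" in phenotype.columns:
            breeds = tuple(sorted(set(phenotype["breed"].to_numpy()[carrier & belted])))
        counts = {}
        for g in sorted(set(groups[carrier & belted])):
            counts[g] = int(((groups == g) & carrier & belted).sum())
        out.append(
            CandidateHaplotype(
                start_snp=s,
                end_snp=e,
                start_bp=int(panel.pos[s]),
                end_bp=int(panel.pos[e]),
                n_snps=e - s + 1,
                alleles="".join(str(a) for a in alleles),
                carrier_breeds=breeds,
                carrier_counts=counts,
            )
        )
    return out


def _merge_candidates(candidates, H, belted, nonbelted):
    """Merge overlapping, allele-consistent qualifying windows into maximal blocks.

    Two windows merge iff they overlap, agree on the shared SNPs, and the
    merged allele string itself still satisfies the presence/absence
    criterion. Blocks contained in a larger block are dropped.
    """
    items = [(s, e, dict(zip(range(s, e + 1), a))) for s, e, a in candidates]
    changed = True
    while changed:
        changed = False
        out = []
        used = [False] * len(items)
        for i in range(len(items)):
            if used[i]:
                continue
            s1, e1, a1 = items[i]
            for j in range(i + 1, len(items)):
                if used[j]:
                    continue
                s2, e2, a2 = items[j]
                if e1 < s2 or e2 < s1:
                    continue
                shared = range(max(s1, s2), min(e1, e2) + 1)
                if any(a1[k] != a2[k] for k in shared):
                    continue
                s, e = min(s1, s2), max(e1, e2)
                a = {**a2, **a1}
                if len(a) != e - s + 1:
                    continue
                arr = np.asarray([a[k] for k in range(s, e + 1)], dtype=H.dtype)
                if not _qualifies(H[:, :, s : e + 1], arr, belted, nonbelted):
                    continue
                s1, e1, a1 = s, e, a
                used[j] = True
                changed = True
            used[i] = True
            out.append((s1, e1, a1))
        items = out
    # drop blocks strictly contained in another with agreeing alleles
    result = []
    for i, (s1, e1, a1) in enumerate(items):
        contained = any(
            j != i
            and s2 <= s1
            and e1 <= e2
            and all(a2[k] == a1[k] for k in range(s1, e1 + 1))
            and (s2, e2) != (s1, e1)
            for j, (s2, e2, a2) in enumerate(items)
        )
        if not contained:
            tup = (s1, e1, tuple(a1[k] for k in range(s1, e1 + 1)))
            if tup not in result:
                result.append(tup)
    return result


def intersect_breed_haplotypes(haplotypes: dict, pos: np.ndarray | None = None) -> list:
    """Maximal SNP intervals on which all supplied haplotypes agree.

    ``haplotypes`` maps a label (e.g. a breed's majority belt haplotype) to
    an equal-length allele vector over the interval. Returns a list of
    ``(start_snp, end_snp_inclusive, allele string)`` tuples, with bp bounds
    appended when ``pos`` is given.
    """
    mats = [np.asarray(v) for v in haplotypes.values()]
    if len(mats) < 1:
        raise ValueError("need at least one haplotype")
    L = len(mats[0])
    if any(len(v) != L for v in mats):
        raise ValueError("haplotypes must have equal length")
    stack = np.stack(mats)
    agree = np.all(stack == stack[0], axis=0)
    out = []
    i = 0
    while i < L:
        if agree[i]:
            j = i
            while j + 1 < L and agree[j + 1]:
                j += 1
            alleles = "".join(str(int(a)) for a in stack[0, i : j + 1])
            if pos is not None:
                out.append((i, j, alleles, int(pos[i]), int(pos[j])))
            else:
                out.append((i, j, alleles))
            i = j + 1
        else:
            i += 1
    return out


def ichaps_to_frame(ichaps: list) -> pd.DataFrame:
    """Tabular output: haplotype id, n_snps, start/end bp, allele string."""
    rows = [
        (f"IC-Hap{i + 1}", h.n_snps, h.start_bp, h.end_bp, h.alleles)
        for i, h in enumerate(ichaps)
    ]
    return pd.DataFrame(rows, columns=["haplotype", "n_snps", "start_bp", "end_bp", "alleles"])
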