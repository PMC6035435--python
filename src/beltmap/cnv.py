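"""Copy-number quantification of the tandem multiplication event.

Four independent lines of evidence are implemented:

* **read depth**: mean depth over the candidate segment divided by mean
  depth over reference intervals; a non-carrier diploid gives ratio 1, a
  heterozygous carrier of a k-copy tandem allele (k+1)/2, a homozygous
  carrier k (2.5 and 4 for the default k = 4);
* **qPCR**: relative quantification against a standard curve fitted to a
  serial dilution series, target over reference amplicon;
* **split reads**: a head-to-tail tandem of k units has k-1 internal
  junctions, so the junction-spanning read count S at per-junction coverage
  c gives k = round_half_up(S/c) + 1;
* **soft-clip consensus**: clipped tails of reads at one array boundary are
  collapsed to a majority consensus whose exact match in the reference
  locates the partner breakpoint.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

GENOTYPE_CLASSES = ("noncarrier", "het_carrier", "hom_carrier")


class BreakpointUnresolvedError(RuntimeError):
    """Raised when the clip consensus has no exact match in the reference."""

    def __init__(self, consensus: str, message: str = "breakpoint unresolved"):
        super().__init__(f"{message}; consensus={consensus}")
        self.consensus = consensus


@dataclass
class CopyNumberCall:
    ratio: float  # candidate / reference, unitless
    copies: int  # estimated copies per diplotype = round(2 * ratio)
    genotype_class: str  # noncarrier | het_carrier | hom_carrier
    method: str  # depth | qpcr | junction


@dataclass
class BreakpointPair:
    left: int  # 1-based reference coordinate
    right: int
    consensus: str
    support: int

    def __post_init__(self) -> None:
        if self.left >= self.right:
            raise ValueError("left breakpoint must precede right breakpoint")


@dataclass
class StandardCurve:
    intercept: float  # Cq units
    slope: float  # Cq per log10 quantity
    r_squared: float

    @property
    def efficiency(self) -> float:
        """Amplification efficiency E = 10^(-1/slope) - 1 (1.0 = perfect doubling)."""
        return 10.0 ** (-1.0 / self.slope) - 1.0

    def quantity(self, cq) -> np.ndarray:
        """Invert the curve: quantity = 10^((Cq - a) / b)."""
        return 10.0 ** ((np.asarray(cq, dtype=float) - self.intercept) / self.slope)


def expected_ratios(k: int = 4) -> tuple:
    """Expected depth/qPCR ratios for the three diplotype classes."""
    return (1.0, (k + 1) / 2.0, float(k))


def classify_ratio(ratio: float, k: int = 4) -> str:
    """Nearest-expected-ratio genotype class (monotone step function)."""
    exp = np.asarray(expected_ratios(k))
    return GENOTYPE_CLASSES[int(np.argmin(np.abs(exp - ratio)))]


def _call(ratio: float, method: str, k: int) -> CopyNumberCall:
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    copies = int(np.floor(2.0 * ratio + 0.5))
    return CopyNumberCall(ratio=float(ratio), copies=copies, genotype_class=classify_ratio(ratio, k), method=method)


# ----------------------------------------------------------------------
def depth_ratio(
    depth: np.ndarray,
    track_start: int,
    candidate: tuple,
    references: list,
    k: int = 4,
) -> CopyNumberCall:
    """Fold change of mean depth: candidate interval over reference intervals.

    Intervals are 1-based inclusive; ``track_start`` is the position of
    ``depth[0]``.
    """
    depth = np.asarray(depth, dtype=float)

    def mean_over(iv):
        s, e = int(iv[0]) - track_start, int(iv[1]) - track_start + 1
        if s < 0 or e > len(depth) or s >= e:
            raise ValueError(f"interval {iv} outside depth track")
        return depth[s:e]

    cand = mean_over(candidate).mean()
    ref = np.concatenate([mean_over(iv) for iv in references]).mean()
    if ref <= 0:
        raise ValueError("zero reference depth")
    return _call(cand / ref, "depth", k)


# ----------------------------------------------------------------------
def fit_standard_curve(quantities: np.ndarray, cq: np.ndarray) -> StandardCurve:
    """Least-squares line Cq = a + b * log10(quantity)."""
    q = np.asarray(quantities, dtype=float)
    c = np.asarray(cq, dtype=float)
    if len(q) != len(c) or len(q) < 2:
        raise ValueError("need >= 2 (quantity, Cq) pairs")
    if len(q) == 2:
        warnings.warn("standard curve fitted to only two points (R^2 = 1 by construction)")
    res = stats.linregress(np.log10(q), c)
    curve = StandardCurve(intercept=float(res.intercept), slope=float(res.slope), r_squared=float(res.rvalue**2))
    if curve.slope >= 0 or not (0.0 < curve.efficiency <= 1.1):
        warnings.warn(f"efficiency out of range: slope={curve.slope:.4g}")
    return curve


def qpcr_copy_ratio(
    qpcr: pd.DataFrame,
    sample: str,
    target: str = "belt2",
    reference: str = "lpo",
    k: int = 4,
) -> CopyNumberCall:
    """Relative copy-number ratio of a sample from a qPCR table.

    The table must contain standard-curve rows (``sample == 'std'`` with a
    ``dilution`` column; standard quantity = 2 * dilution, i.e. a 2-copy
    reference DNA) and the sample's Cq for both amplicons. Each amplicon is
    quantified against its own curve; the call is the target/reference
    quantity ratio.
    """
    out = {}
    for amp in (target, reference):
        std = qpcr[(qpcr["sample"] == "std") & (qpcr["amplicon"] == amp)]
        if len(std) < 2:
            raise ValueError(f"no standard curve for amplicon {amp!r}")
        curve = fit_standard_curve(2.0 * std["dilution"].to_numpy(), std["Cq"].to_numpy())
        row = qpcr[(qpcr["sample"] == sample) & (qpcr["amplicon"] == amp)]
        if row.empty:
            raise ValueError(f"no Cq for sample {sample!r}, amplicon {amp!r}")
        out[amp] = float(np.mean(curve.quantity(row["Cq"].to_numpy())))
    return _call(out[target] / out[reference], "qpcr", k)


# ----------------------------------------------------------------------
def junction_copies(split_read_count: int, junction_cov: float, carrier_haplotypes: int = 1) -> int:
    """Tandem copies per carrier haplotype from the junction-spanning read count.

    ``J = round_half_up(S / c)`` junctions imply ``k = J + 1`` tandem copies
    (a head-to-tail array of k units has k-1 internal junctions). ``c`` is
    the expected coverage of a single junction; with more than one carrier
    haplotype the count is shared between them.
    """
    if junction_cov <= 0:
        raise ValueError("junction coverage must be positive")
    if carrier_haplotypes < 1:
        raise ValueError("carrier_haplotypes must be >= 1")
    j = int(np.floor(split_read_count / (junction_cov * carrier_haplotypes) + 0.5))
    return j + 1


# ----------------------------------------------------------------------
def _mode_smallest(values) -> int:
    vals, counts = np.unique(np.asarray(values), return_counts=True)
    return int(vals[counts == counts.max()].min())  # tie -> smaller coordinate


def _column_consensus(seqs: list, right_aligned: bool, min_majority: float) -> str:
    """Per-column majority consensus; an ambiguous column truncates."""
    if right_aligned:
        seqs = [s[::-1] for s in seqs]
    out = []
    for col in range(max(len(s) for s in seqs)):
        bases = [s[col] for s in seqs if len(s) > col]
        if not bases:
            break
        vals, counts = np.unique(bases, return_counts=True)
        if counts.max() / len(bases) < min_majority:
            break
        out.append(str(vals[np.argmax(counts)]))
    cons = "".join(out)
    return cons[::-1] if right_aligned else cons


def breakpoints_from_clips(
    split_reads: pd.DataFrame,
    ref_seq: str,
    ref_offset: int = 1,
    min_support: int = 2,
    min_consensus_len: int = 15,
    min_majority: float = 0.6,
) -> BreakpointPair:
    """Infer the breakpoint pair of a head-to-tail tandem from soft clips.

    Records are grouped by clip side; the mode of the mapped endpoints on
    the better-supported side (ties broken towards 'right', then towards the
    smaller coordinate) gives one breakpoint, and the exact match of the
    clip consensus in ``ref_seq`` (whose first base sits at 1-based position
    ``ref_offset``) gives the partner breakpoint.
    """
    counts = split_reads["clip_side"].value_counts()
    n_right = int(counts.get("right", 0))
    n_left = int(counts.get("left", 0))
    if max(n_right, n_left) < min_support:
        raise ValueError("insufficient support: need >= 2 records on one side")
    side = "right" if n_right >= n_left else "left"
    recs = split_reads[split_reads["clip_side"] == side]

    if side == "right":
        anchor = _mode_smallest(recs["mapped_end"])  # the right breakpoint
        cons = _column_consensus(list(recs["clip_seq"]), right_aligned=False, min_majority=min_majority)
    else:
        anchor = _mode_smallest(recs["mapped_start"])  # the left breakpoint
        cons = _column_consensus(list(recs["clip_seq"]), right_aligned=True, min_majority=min_majority)
    if len(cons) < min_consensus_len:
        raise BreakpointUnresolvedError(cons, "consensus too short")

    hit = ref_seq.find(cons)
    if hit < 0:
        raise BreakpointUnresolvedError(cons)
    if side == "right":
        left, right = ref_offset + hit, anchor
    else:
        left, right = anchor, ref_offset + hit + len(cons) - 1
    return BreakpointPair(left=int(left), right=int(right), consensus=cons, support=int(len(recs)))


# ----------------------------------------------------------------------
def filter_private_variants(
    variants: pd.DataFrame,
    hom_cases: list,
    het_cases: list,
    controls: list,
) -> pd.DataFrame:
    """Case/control candidate-variant filter on a genotype table.

    ``variants`` holds one row per variant with one dosage column (0/1/2)
    per animal. A variant survives iff it is hom-alt (2) in every
    ``hom_cases`` animal, het (1) in every obligate-het ``het_cases``
    animal, and hom-ref (0) in every control.
    """
    keep = np.ones(len(variants), dtype=bool)
    for a in hom_cases:
        keep &= variants[a].to_numpy() == 2
    for a in het_cases:
        keep &= variants[a].to_numpy() == 1
    for a in controls:
        keep &= variants[a].to_numpy() == 0
    return variants[keep]


def calls_to_frame(calls: dict) -> pd.DataFrame:
    """Tabulate {animal_id: CopyNumberCall} as animal, method, ratio, copies, class."""
    rows = [
        (aid, c.method, c.ratio, c.copies, c.genotype_class) for aid, c in calls.items()
    ]
    return pd.DataFrame(rows, columns=["animal_id", "method", "ratio", "copies", "genotype_class"])
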