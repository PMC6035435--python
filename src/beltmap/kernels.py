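"""Genomic relationship and local haplotype-IBD kernels.

Two kernels enter the mixed model:

* the genome-wide **unified additive relationship (UAR)** matrix built from
  standardized SNP dosages, whose leading principal components act as fixed
  covariates against population stratification and family structure;
* a per-window **haplotype IBD** matrix ``G`` (2n x 2n) converted to an
  animal-level **diplotype relationship matrix** ``D`` (n x n) via the
  2-haplotypes-per-animal incidence ``K``: ``D = 1/2 * K G K'``.

The default local IBD kernel is a run-length similarity surrogate: scanning
outward from the window midpoint, ``l`` (resp. ``r``) consecutive identical
alleles to the left (right) give ``G(a,b) = l*r / (half_window)^2`` with
``G(a,a) = 1``. It is fully determined by the marker data (no effective
population size or mutation age is needed) and is monotone in the length of
the shared haplotype around the midpoint. Any callable with the same
signature can be plugged in instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .panel import PhasedPanel


class MonomorphicSNPError(ValueError):
    """A monomorphic SNP reached the UAR; MAF filtering must happen upstream."""


@dataclass
class UarMatrix:
    matrix: np.ndarray  # (n, n) symmetric
    n_snps: int


@dataclass
class PcSet:
    """Leading eigenpairs of the UAR explaining a target share of variance."""

    eigenvalues: np.ndarray  # all eigenvalues, descending
    m: int  # minimal count whose positive-eigenvalue share exceeds threshold
    scores: np.ndarray  # (n, m) component scores used as fixed covariates


@dataclass
class WindowKernel:
    window_index: int  # index of the first SNP of the window
    midpoint_bp: float  # midpoint between the two central SNPs
    G: np.ndarray  # (2n, 2n) haplotype IBD
    D: np.ndarray  # (n, n) diplotype relationship (PSD-repaired)
    repaired: bool


def allele_frequencies(genotypes: np.ndarray) -> np.ndarray:
    """ALT allele frequency per SNP from a complete dosage matrix."""
    g = np.asarray(genotypes, dtype=float)
    return g.mean(axis=0) / 2.0


def uar(genotypes: np.ndarray, p: np.ndarray | None = None) -> UarMatrix:
    """Unified additive relationship matrix from dosages in {0, 1, 2}.

    Off-diagonal: ``A_jk = (1/N) sum_i (x_ij - 2p_i)(x_ik - 2p_i) / (2p_i(1-p_i))``.
    Diagonal: ``A_jj = 1 + (1/N) sum_i (x_ij^2 - (1+2p_i)x_ij + 2p_i^2) / (2p_i(1-p_i))``.

    Frequencies default to estimates from the analyzed animals themselves.
    """
    x = np.asarray(genotypes, dtype=float)
    if x.ndim != 2:
        raise ValueError("genotypes must be (n_animals, n_snps)")
    if np.any(x < 0):
        raise ValueError("missing genotypes not allowed in UAR")
    p = allele_frequencies(x) if p is None else np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise MonomorphicSNPError("monomorphic SNP present; filter MAF upstream")
    n, N = x.shape
    denom = 2.0 * p * (1.0 - p)
    z = (x - 2.0 * p) / np.sqrt(denom)
    A = (z @ z.T) / N
    diag = 1.0 + ((x * x - (1.0 + 2.0 * p) * x + 2.0 * p * p) / denom).sum(axis=1) / N
    np.fill_diagonal(A, diag)
    return UarMatrix((A + A.T) / 2.0, N)


def principal_components(uar_matrix: UarMatrix | np.ndarray, var_threshold: float = 0.95) -> PcSet:
    """Eigendecomposition of the UAR; keep the minimal component count whose
    eigenvalue sum exceeds ``var_threshold`` of the total positive-eigenvalue
    variance. Scores (eigenvectors scaled by sqrt eigenvalue) serve as fixed
    covariates."""
    A = uar_matrix.matrix if isinstance(uar_matrix, UarMatrix) else np.asarray(uar_matrix)
    w, V = np.linalg.eigh(A)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    pos = np.clip(w, 0.0, None)
    total = pos.sum()
    if total <= 0:
        raise ValueError("UAR has no positive eigenvalues")
    cum = np.cumsum(pos)
    m = int(np.searchsorted(cum, var_threshold * total, side="right")) + 1
    m = min(m, len(w))
    scores = V[:, :m] * np.sqrt(pos[:m])
    return PcSet(eigenvalues=w, m=m, scores=scores)


def parallel_analysis_components(
    genotypes: np.ndarray,
    p: np.ndarray | None = None,
    n_iter: int = 20,
    quantile: float = 0.95,
    seed: int = 0,
) -> PcSet:
    """Horn's parallel analysis on the UAR eigenspectrum.

    Retains the leading components whose eigenvalues exceed the ``quantile``
    of the rank-matched eigenvalues of UAR matrices built from genotypes
    permuted independently per SNP (which destroys relatedness and LD while
    keeping allele frequencies). This keeps the structural spikes — breeds,
    families — and drops the sampling-noise bulk, so it typically retains
    far fewer components than the cumulative-variance rule.
    """
    x = np.asarray(genotypes, dtype=float)
    A = uar(x, p)
    w_obs = np.sort(np.linalg.eigvalsh(A.matrix))[::-1]
    rng = np.random.default_rng(seed)
    null = np.empty((n_iter, len(w_obs)))
    xp = x.copy()
    for it in range(n_iter):
        for i in range(x.shape[1]):
            rng.shuffle(xp[:, i])
        null[it] = np.sort(np.linalg.eigvalsh(uar(xp, p).matrix))[::-1]
    thr = np.quantile(null, quantile, axis=0)
    m = 0
    while m < len(w_obs) and w_obs[m] > thr[m]:
        m += 1
    m = max(m, 1)
    w, V = np.linalg.eigh(A.matrix)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    scores = V[:, :m] * np.sqrt(np.clip(w[:m], 0.0, None))
    return PcSet(eigenvalues=w, m=m, scores=scores)


# ----------------------------------------------------------------------
# local haplotype IBD
def locibd_window(hap_window: np.ndarray, half: int | None = None) -> np.ndarray:
    """Run-length similarity kernel over one SNP window.

    Parameters
    ----------
    hap_window : (2n, w) int array of haplotype alleles over an even-length
        window; the midpoint lies between columns w/2-1 and w/2.

    Returns the (2n, 2n) matrix ``G`` with ``G(a,b) = l*r / (w/2)^2`` where
    ``l``/``r`` count consecutive identical alleles scanning outward from
    the midpoint, and unit diagonal. Missing alleles (negative codes) never
    match, which conservatively shortens shared runs.
    """
    H = np.asarray(hap_window)
    nh, w = H.shape
    if w % 2 != 0:
        raise ValueError("window length must be even")
    S = w // 2 if half is None else half

    def _run(cols) -> np.ndarray:
        run = np.zeros((nh, nh), dtype=np.int32)
        alive = np.ones((nh, nh), dtype=bool)
        for c in cols:
            col = H[:, c]
            eq = (col[:, None] == col[None, :]) & (col[:, None] >= 0)
            alive &= eq
            run += alive
        return run

    left = _run(range(S - 1, -1, -1))
    right = _run(range(S, w))
    G = (left * right).astype(np.float64) / (S * S)
    np.fill_diagonal(G, 1.0)
    return G


def diplotype_matrix(G: np.ndarray, repair: bool = True):
    """Convert a 2n x 2n haplotype kernel into the n x n diplotype matrix.

    ``D_jk = 1/2 (G(pj,pk) + G(pj,mk) + G(mj,pk) + G(mj,mk))`` for j != k and
    ``D_jj = 1 + G(pj,mj)`` — equivalently ``D = 1/2 K G K'`` with haplotypes
    2j, 2j+1 belonging to animal j. Negative eigenvalues (possible under the
    surrogate kernel) are clipped to zero, with a tiny diagonal jitter if the
    clipped matrix is still numerically indefinite, because REML needs a
    valid covariance.
    """
    G = np.asarray(G, dtype=np.float64)
    if G.shape[0] != G.shape[1] or G.shape[0] % 2 != 0:
        raise ValueError("G must be square with even dimension")
    D = 0.5 * (G[0::2, 0::2] + G[0::2, 1::2] + G[1::2, 0::2] + G[1::2, 1::2])
    D = (D + D.T) / 2.0
    repaired = False
    if repair:
        wmin = np.linalg.eigvalsh(D)[0]
        if wmin < -1e-10:
            w, V = np.linalg.eigh(D)
            D = (V * np.clip(w, 0.0, None)) @ V.T
            D = (D + D.T) / 2.0
            repaired = True
            if np.linalg.eigvalsh(D)[0] < -1e-10:
                D = D + 1e-8 * np.eye(D.shape[0])
    return D, repaired


def iter_window_kernels(panel: PhasedPanel, window: int = 40, step: int = 1, kernel=locibd_window):
    """Yield a WindowKernel for every full window of `window` SNPs.

    Windows shorter than `window` at the chromosome edge are skipped.
    """
    if window % 2 != 0:
        raise ValueError("window size must be even")
    H = panel.hap_matrix()
    m = panel.n_snps
    half = window // 2
    for s in range(0, m - window + 1, step):
        G = kernel(H[:, s : s + window])
        D, repaired = diplotype_matrix(G)
        mid = (panel.pos[s + half - 1] + panel.pos[s + half]) / 2.0
        yield WindowKernel(window_index=s, midpoint_bp=mid, G=G, D=D, repaired=repaired)


def write_lower_triangle(matrix: np.ndarray, ids, path) -> None:
    """Whitespace-delimited lower-triangle dump with an id header row."""
    with open(path, "w") as fh:
        fh.write(" ".join(map(str, ids)) + "\n")
        for j in range(matrix.shape[0]):
            fh.write(" ".join(f"{matrix[j, k]:.6g}" for k in range(j + 1)) + "\n")
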