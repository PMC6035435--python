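"""Variance-component scan: REML mixed model, LRT profile, 2-LOD interval.

At the midpoint of every sliding SNP window the model

    y = X beta + Z q + e,    q ~ N(0, D sigma_q^2),   e ~ N(0, I sigma_e^2)

is fitted by REML, where ``y`` holds the numeric phenotype codes, ``X`` the
intercept plus UAR principal-component scores, and ``D`` the window's
diplotype relationship matrix (Z = I, one record per animal). Writing
``gamma = sigma_q^2 / sigma_e^2`` and ``V = sigma_e^2 (I + gamma D)``, one
eigendecomposition of ``D`` rotates the problem so the restricted likelihood
is a cheap 1-D function of ``gamma``; ``sigma_e^2`` is profiled analytically.

The test statistic is ``LRT = 2 (l_alt - l_null)``, clamped at zero (the null
lies on the boundary ``gamma = 0``, so the chi-square(1) reference is
conservative). One LOD unit equals ``2 ln 10 = 4.605`` LRT units; the
confidence interval is the contiguous run of window midpoints around the
peak within a 2-LOD drop, extended by 20 SNP positions on each side.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .kernels import iter_window_kernels, locibd_window
from .panel import PhasedPanel

logger = logging.getLogger(__name__)

LOD_IN_LRT = 2.0 * np.log(10.0)  # 4.605...

_LOG10_GAMMA_LO = -8.0


@dataclass
class MixedModelFit:
    sigma_q2: float
    sigma_e2: float
    gamma: float
    loglik: float
    converged: bool
    identifiable: bool = True


@dataclass
class ScanProfile:
    """Per-window LRT profile, ordered by midpoint bp."""

    table: pd.DataFrame  # window_index, midpoint_bp, lrt, sigma_q2, sigma_e2
    pos: np.ndarray  # SNP positions of the scanned panel
    window: int
    null_loglik: float

    @property
    def peak_index(self) -> int:
        """Row index of the LRT maximum (first one on ties)."""
        return int(self.table["lrt"].to_numpy().argmax())

    @property
    def lrt_max(self) -> float:
        return float(self.table["lrt"].max())

    @property
    def peak_midpoint_bp(self) -> float:
        return float(self.table["midpoint_bp"].iloc[self.peak_index])

    def to_tsv(self, path) -> None:
        out = self.table.rename(columns={"lrt": "LRT"})
        out.to_csv(path, sep="\t", index=False)


@dataclass
class ConfidenceInterval:
    """2-LOD-drop interval around the peak, plus its 20-SNP extension."""

    initial_bp: tuple  # (lo, hi) window-midpoint bp
    extended_bp: tuple  # (lo, hi) SNP-position bp after extension
    initial_windows: tuple  # (first, last) row indices into the profile
    extended_snps: tuple  # (first, last) SNP indices
    peak_midpoint_bp: float

    def to_bed(self, path, chrom: str) -> None:
        """BED output: 0-based half-open, converted from 1-based inclusive."""
        with open(path, "w") as fh:
            fh.write("# 0-based half-open intervals (converted from 1-based inclusive bp)\n")
            lo, hi = self.initial_bp
            fh.write(f"{chrom}\t{int(lo) - 1}\t{int(hi)}\tinitial_CI\n")
            lo, hi = self.extended_bp
            fh.write(f"{chrom}\t{int(lo) - 1}\t{int(hi)}\textended_CI\n")


# ----------------------------------------------------------------------
def _drop_rank_deficient(X: np.ndarray) -> np.ndarray:
    """Drop linearly dependent columns (QR with column pivoting)."""
    from scipy.linalg import qr

    _, R, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    keep = np.sort(piv[: int((diag > tol).sum())])
    if len(keep) < X.shape[1]:
        logger.warning("dropping %d rank-deficient covariate column(s)", X.shape[1] - len(keep))
    return X[:, keep]


def _profiled_reml(gamma: float, lam: np.ndarray, yt: np.ndarray, Xt: np.ndarray) -> tuple:
    """Restricted log-likelihood profiled over sigma_e^2, in rotated coordinates.

    lam are the eigenvalues of D; yt, Xt are U'y and U'X.
    """
    n, p = Xt.shape
    w = 1.0 / (1.0 + gamma * lam)
    XtW = Xt * w[:, None]
    XtWX = Xt.T @ XtW
    XtWy = XtW.T @ yt
    sign, logdet_xwx = np.linalg.slogdet(XtWX)
    if sign <= 0:
        return -np.inf, np.nan
    beta = np.linalg.solve(XtWX, XtWy)
    ypy = float(yt @ (w * yt) - XtWy @ beta)
    dof = n - p
    if ypy <= 0:
        return -np.inf, np.nan
    sigma_e2 = ypy / dof
    logdet_h = float(np.sum(np.log1p(gamma * lam)))
    ll = -0.5 * (dof * (np.log(2 * np.pi) + 1.0 + np.log(sigma_e2)) + logdet_h + logdet_xwx)
    return ll, sigma_e2


def reml_fit(
    y: np.ndarray,
    X: np.ndarray,
    D: np.ndarray,
    gamma_max: float = 1e6,
    xtol: float = 1e-8,
    _eig=None,
) -> MixedModelFit:
    """REML fit of the single-kernel mixed model.

    Maximizes the restricted likelihood over ``gamma`` in ``[0, gamma_max]``
    by a coarse grid on log10 gamma followed by bounded 1-D refinement, after
    a single eigendecomposition of ``D``. ``gamma = 0`` reduces to the null
    (no-locus) model. Deterministic given its inputs.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = len(y)
    if X.shape[0] != n or D.shape != (n, n):
        raise ValueError("y, X and D must have aligned rows")
    X = _drop_rank_deficient(X)
    p = X.shape[1]
    if n <= p + 1:
        raise ValueError("no residual degrees of freedom")

    if _eig is None:
        lam, U = np.linalg.eigh(D)
        if lam[0] < -1e-8:
            raise ValueError("D is not positive semidefinite (repair upstream)")
        lam = np.clip(lam, 0.0, None)
    else:
        lam, U = _eig
    yt = U.T @ y
    Xt = U.T @ X

    ll0, se0 = _profiled_reml(0.0, lam, yt, Xt)

    if np.allclose(D, np.eye(n), atol=1e-12):
        # sigma_q^2 and sigma_e^2 are confounded: flag, LRT = 0 by convention
        return MixedModelFit(0.0, se0, 0.0, ll0, converged=True, identifiable=False)

    def neg(log10g: float) -> float:
        return -_profiled_reml(10.0**log10g, lam, yt, Xt)[0]

    hi = np.log10(gamma_max)
    grid = np.linspace(_LOG10_GAMMA_LO, hi, 29)
    vals = np.array([neg(g) for g in grid])
    k = int(np.argmin(vals))
    lo_b = grid[max(0, k - 1)]
    hi_b = grid[min(len(grid) - 1, k + 1)]
    res = minimize_scalar(neg, bounds=(lo_b, hi_b), method="bounded", options={"xatol": xtol})
    best_ll = -res.fun
    gamma = 10.0**res.x
    if ll0 >= best_ll:
        best_ll, gamma = ll0, 0.0
    _, sigma_e2 = _profiled_reml(gamma, lam, yt, Xt)
    return MixedModelFit(
        sigma_q2=gamma * sigma_e2,
        sigma_e2=sigma_e2,
        gamma=gamma,
        loglik=best_ll,
        converged=bool(res.success),
    )


def null_reml_fit(y: np.ndarray, X: np.ndarray) -> MixedModelFit:
    """REML of the fixed-effects-only model (gamma = 0)."""
    y = np.asarray(y, dtype=float).ravel()
    X = _drop_rank_deficient(np.atleast_2d(np.asarray(X, dtype=float)))
    n, p = X.shape
    if n <= p + 1:
        raise ValueError("no residual degrees of freedom")
    lam = np.zeros(n)
    ll0, se0 = _profiled_reml(0.0, lam, y, X)
    return MixedModelFit(0.0, se0, 0.0, ll0, converged=True)


# ----------------------------------------------------------------------
def lrt_scan(
    panel: PhasedPanel,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
    window: int = 40,
    step: int = 1,
    kernel=locibd_window,
) -> ScanProfile:
    """Slide `window`-SNP windows across the panel and fit each midpoint.

    ``covariates`` are the PC scores (the intercept is added here). LRT
    values are clamped at zero.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = panel.n_animals
    if len(y) != n:
        raise ValueError("phenotype length does not match panel")
    ones = np.ones((n, 1))
    X = ones if covariates is None else np.hstack([ones, np.atleast_2d(covariates)])
    X = _drop_rank_deficient(X)

    null = null_reml_fit(y, X)
    rows = []
    if np.ptp(y) == 0:
        # constant response: no variance to partition anywhere
        for wk in iter_window_kernels(panel, window=window, step=step, kernel=kernel):
            rows.append((wk.window_index, wk.midpoint_bp, 0.0, 0.0, 0.0))
    else:
        for wk in iter_window_kernels(panel, window=window, step=step, kernel=kernel):
            fit = reml_fit(y, X, wk.D)
            lrt = max(0.0, 2.0 * (fit.loglik - null.loglik)) if fit.identifiable else 0.0
            rows.append((wk.window_index, wk.midpoint_bp, lrt, fit.sigma_q2, fit.sigma_e2))
    table = pd.DataFrame(
        rows, columns=["window_index", "midpoint_bp", "lrt", "sigma_q2", "sigma_e2"]
    ).sort_values("midpoint_bp", ignore_index=True)
    return ScanProfile(table=table, pos=panel.pos.copy(), window=window, null_loglik=null.loglik)


def lod_drop_ci(profile: ScanProfile, drop_lod: float = 2.0, extend_snps: int = 20) -> ConfidenceInterval:
    """Confidence interval by the LOD drop-off criterion.

    The initial interval is the maximal contiguous run of window midpoints
    containing the peak with ``LRT >= LRT_max - drop_lod * 4.605``; it is
    then widened by ``extend_snps`` SNP positions on each side (truncated at
    the chromosome ends) because each LRT value only represents a window
    midpoint.
    """
    t = profile.table
    lrt = t["lrt"].to_numpy()
    peak = profile.peak_index
    thr = lrt[peak] - drop_lod * LOD_IN_LRT
    lo = peak
    while lo > 0 and lrt[lo - 1] >= thr:
        lo -= 1
    hi = peak
    while hi < len(lrt) - 1 and lrt[hi + 1] >= thr:
        hi += 1
    initial_bp = (float(t["midpoint_bp"].iloc[lo]), float(t["midpoint_bp"].iloc[hi]))

    half = profile.window // 2
    m = len(profile.pos)
    left_snp = int(t["window_index"].iloc[lo]) + half - 1  # SNP left of the lo midpoint
    right_snp = int(t["window_index"].iloc[hi]) + half  # SNP right of the hi midpoint
    ext_lo = max(0, left_snp - extend_snps)
    ext_hi = min(m - 1, right_snp + extend_snps)
    extended_bp = (float(profile.pos[ext_lo]), float(profile.pos[ext_hi]))
    return ConfidenceInterval(
        initial_bp=initial_bp,
        extended_bp=extended_bp,
        initial_windows=(lo, hi),
        extended_snps=(ext_lo, ext_hi),
        peak_midpoint_bp=profile.peak_midpoint_bp,
    )
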