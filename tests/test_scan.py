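"""REML mixed-model fit, LRT scan and LOD-drop confidence interval."""

import numpy as np
import pandas as pd
import pytest

import beltmap as bm
from beltmap.scan import (
    LOD_IN_LRT,
    ScanProfile,
    lod_drop_ci,
    lrt_scan,
    null_reml_fit,
    reml_fit,
)


def naive_restricted_loglik(y, X, D, gamma):
    """Direct evaluation from the covariance matrix (independent oracle)."""
    n, p = X.shape
    H = np.eye(n) + gamma * D
    Hi = np.linalg.inv(H)
    XtHiX = X.T @ Hi @ X
    beta = np.linalg.solve(XtHiX, X.T @ Hi @ y)
    r = y - X @ beta
    s2 = (r @ Hi @ r) / (n - p)
    _, ld_h = np.linalg.slogdet(H)
    _, ld_x = np.linalg.slogdet(XtHiX)
    return -0.5 * ((n - p) * (np.log(2 * np.pi) + 1 + np.log(s2)) + ld_h + ld_x)


def _random_instance(seed, n=40):
    rng = np.random.default_rng(seed)
    B = rng.normal(size=(n, 5))
    D = B @ B.T / 5
    d = np.sqrt(np.diag(D))
    D = D / np.outer(d, d)
    X = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
    L = np.linalg.cholesky(D + 1e-8 * np.eye(n))
    y = X @ rng.normal(size=3) + L @ rng.normal(size=n) + rng.normal(size=n)
    return y, X, D


class TestRemlFit:
    def test_identity_kernel_is_flagged_unidentifiable(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=30)
        X = np.ones((30, 1))
        fit = reml_fit(y, X, np.eye(30))
        assert not fit.identifiable
        assert fit.gamma == 0.0

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_optimum_matches_grid_search_oracle(self, seed):
        """Optimizer log-likelihood within 1e-6 of a 2000-point grid over
        log10 gamma in [-6, 6]."""
        y, X, D = _random_instance(seed)
        fit = reml_fit(y, X, D)
        grid = 10.0 ** np.linspace(-6, 6, 2000)
        grid_best = max(naive_restricted_loglik(y, X, D, g) for g in grid)
        grid_best = max(grid_best, naive_restricted_loglik(y, X, D, 0.0))
        assert fit.loglik >= grid_best - 1e-6
        # and the profiled likelihood agrees with the naive formula
        assert fit.loglik == pytest.approx(
            naive_restricted_loglik(y, X, D, fit.gamma), abs=1e-6
        )

    def test_variance_recovery_on_block_kernel(self):
        """sigma_q^2 = sigma_e^2 = 1 on a block family kernel, n=200:
        mean estimates over 100 replicates within 15% of truth."""
        n, bs = 200, 5
        D = np.kron(np.eye(n // bs), np.ones((bs, bs)))
        L = np.linalg.cholesky(D + 1e-10 * np.eye(n))
        X = np.ones((n, 1))
        rng = np.random.default_rng(12)
        eig = np.linalg.eigh(D)
        sq, se = [], []
        for _ in range(100):
            y = 1.0 + L @ rng.normal(size=n) + rng.normal(size=n)
            fit = reml_fit(y, X, D, _eig=eig)
            sq.append(fit.sigma_q2)
            se.append(fit.sigma_e2)
        assert abs(np.mean(sq) - 1.0) < 0.15
        assert abs(np.mean(se) - 1.0) < 0.15

    def test_no_residual_dof_rejected(self):
        y = np.arange(3.0)
        X = np.column_stack([np.ones(3), np.arange(3.0)])
        with pytest.raises(ValueError, match="degrees of freedom"):
            reml_fit(y, X, np.eye(3) * 2)

    def test_non_psd_kernel_rejected(self):
        rng = np.random.default_rng(5)
        y = rng.normal(size=10)
        D = -np.eye(10)
        with pytest.raises(ValueError, match="positive semidefinite"):
            reml_fit(y, np.ones((10, 1)), D)

    def test_rank_deficient_covariates_dropped(self):
        y, X, D = _random_instance(9)
        X2 = np.column_stack([X, X[:, 1]])  # duplicate column
        f1 = reml_fit(y, X, D)
        f2 = reml_fit(y, X2, D)
        assert f2.loglik == pytest.approx(f1.loglik, abs=1e-8)


class TestLrtScan:
    def test_constant_phenotype_gives_zero_profile(self, small_cohort):
        panel, _, truth = small_cohort
        tp = bm.PhasedPanel(panel.chrom, panel.snp_ids, panel.pos, truth.true_haps, panel.animal_ids)
        prof = lrt_scan(tp, np.full(tp.n_animals, 2.0), window=40, step=20)
        assert (prof.table["lrt"] == 0).all()

    def test_lrt_invariant_to_affine_rescaling(self, small_cohort):
        panel, pheno, truth = small_cohort
        tp = bm.PhasedPanel(panel.chrom, panel.snp_ids, panel.pos, truth.true_haps, panel.animal_ids)
        y = pheno["code"].to_numpy()
        p1 = lrt_scan(tp, y, window=40, step=60)
        p2 = lrt_scan(tp, 3.5 * y - 2.0, window=40, step=60)
        assert np.abs(p1.table["lrt"].to_numpy() - p2.table["lrt"].to_numpy()).max() < 1e-6

    def test_profile_sorted_and_nonnegative(self, small_cohort):
        panel, pheno, truth = small_cohort
        tp = bm.PhasedPanel(panel.chrom, panel.snp_ids, panel.pos, truth.true_haps, panel.animal_ids)
        prof = lrt_scan(tp, pheno["code"].to_numpy(), window=40, step=45)
        mids = prof.table["midpoint_bp"].to_numpy()
        assert (np.diff(mids) > 0).all()
        assert (prof.table["lrt"] >= 0).all()


def _profile_from_lrt(lrt, window=40):
    m = len(lrt) + window - 1
    pos = np.arange(1, m + 1) * 10_000
    rows = []
    for w, v in enumerate(lrt):
        mid = (pos[w + window // 2 - 1] + pos[w + window // 2]) / 2
        rows.append((w, mid, float(v), 0.0, 1.0))
    table = pd.DataFrame(rows, columns=["window_index", "midpoint_bp", "lrt", "sigma_q2", "sigma_e2"])
    return ScanProfile(table=table, pos=pos, window=window, null_loglik=0.0)


class TestLodDropCi:
    def test_triangular_profile_threshold_arithmetic(self):
        """Peak 20, unit steps: the 2-LOD threshold is 20 - 9.21 = 10.79, so
        midpoints with LRT >= 10.79 form the initial interval."""
        lrt = np.concatenate([np.arange(0, 21), np.arange(19, -1, -1)])
        prof = _profile_from_lrt(lrt)
        ci = lod_drop_ci(prof)
        thr = 20 - 2 * LOD_IN_LRT
        in_ci = np.flatnonzero(lrt >= thr)
        mids = prof.table["midpoint_bp"].to_numpy()
        assert ci.initial_bp == (mids[in_ci[0]], mids[in_ci[-1]])
        assert ci.initial_bp[0] <= ci.peak_midpoint_bp <= ci.initial_bp[1]

    def test_single_nonzero_window(self):
        lrt = np.zeros(30)
        lrt[12] = 50.0
        ci = lod_drop_ci(_profile_from_lrt(lrt))
        mids = _profile_from_lrt(lrt).table["midpoint_bp"].to_numpy()
        assert ci.initial_bp == (mids[12], mids[12])

    def test_edge_peak_extension_truncated(self):
        lrt = np.zeros(10)
        lrt[0] = 50.0
        prof = _profile_from_lrt(lrt)
        ci = lod_drop_ci(prof, extend_snps=100)
        assert ci.extended_snps[0] == 0
        assert ci.extended_snps[1] == len(prof.pos) - 1
        assert ci.extended_bp[0] == prof.pos[0]

    def test_extended_contains_initial_and_peak(self, small_cohort):
        panel, pheno, truth = small_cohort
        tp = bm.PhasedPanel(panel.chrom, panel.snp_ids, panel.pos, truth.true_haps, panel.animal_ids)
        prof = lrt_scan(tp, pheno["code"].to_numpy(), window=40, step=25)
        ci = lod_drop_ci(prof)
        assert ci.extended_bp[0] <= ci.initial_bp[0]
        assert ci.extended_bp[1] >= ci.initial_bp[1]
        assert ci.extended_bp[0] <= ci.peak_midpoint_bp <= ci.extended_bp[1]


def test_null_fit_matches_ols_residual_variance():
    rng = np.random.default_rng(4)
    y = rng.normal(size=50)
    X = np.column_stack([np.ones(50), rng.normal(size=50)])
    fit = null_reml_fit(y, X)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    assert fit.sigma_e2 == pytest.approx(r @ r / (50 - 2))
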