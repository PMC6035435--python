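"""Copy-number quantification: depth ratios, standard curves, junction
counting, breakpoint consensus and the private-variant filter."""

import numpy as np
import pandas as pd
import pytest

import beltmap as bm
from beltmap.cnv import (
    BreakpointUnresolvedError,
    classify_ratio,
    expected_ratios,
    filter_private_variants,
)
from conftest import single_animal_truth


class TestDepthRatio:
    def test_uniform_depth_is_noncarrier(self):
        depth = np.full(3000, 25.0)
        call = bm.depth_ratio(depth, 1, (1001, 2000), [(1, 1000), (2001, 3000)])
        assert call.ratio == pytest.approx(1.0)
        assert call.genotype_class == "noncarrier"
        assert call.copies == 2

    def test_invariant_to_uniform_coverage_scaling(self):
        rng = np.random.default_rng(0)
        depth = rng.poisson(30, size=3000).astype(float)
        a = bm.depth_ratio(depth, 1, (1001, 2000), [(1, 1000)])
        b = bm.depth_ratio(depth * 7.3, 1, (1001, 2000), [(1, 1000)])
        assert a.ratio == pytest.approx(b.ratio)

    def test_het_carrier_ratio_concentrates_near_2_5(self):
        """Poisson simulation at 30x: ratio in [2.25, 2.75] in >=95% of
        200 replicates."""
        truth = single_animal_truth(1)
        inside = 0
        for s in range(200):
            ds = bm.simulate_depth(truth, (4000, 6000), [(1000, 3000), (7000, 9000)],
                                   mean_cov=30, seed=s)
            call = bm.depth_ratio(ds.depth["A1"], ds.track_start, (4000, 6000),
                                  [(1000, 3000), (7000, 9000)])
            inside += 2.25 <= call.ratio <= 2.75
        assert inside >= 190

    def test_hom_carrier_classified_with_eight_copies(self):
        truth = single_animal_truth(2)
        ds = bm.simulate_depth(truth, (4000, 6000), [(1000, 3000)], mean_cov=60, seed=1)
        call = bm.depth_ratio(ds.depth["A1"], ds.track_start, (4000, 6000), [(1000, 3000)])
        assert call.genotype_class == "hom_carrier"
        assert call.copies == 8

    def test_zero_reference_depth_errors(self):
        depth = np.zeros(100)
        depth[:50] = 10
        with pytest.raises(ValueError, match="zero reference"):
            bm.depth_ratio(depth, 1, (1, 50), [(51, 100)])

    def test_class_boundaries_are_midpoints(self):
        assert expected_ratios(4) == (1.0, 2.5, 4.0)
        assert classify_ratio(1.74) == "noncarrier"
        assert classify_ratio(1.76) == "het_carrier"
        assert classify_ratio(3.24) == "het_carrier"
        assert classify_ratio(3.26) == "hom_carrier"


class TestStandardCurve:
    def test_perfect_doubling_curve(self):
        curve = bm.fit_standard_curve([1, 0.1, 0.01], [20, 23.3219, 26.6439])
        assert curve.slope == pytest.approx(-3.3219, abs=2e-4)
        assert curve.efficiency == pytest.approx(1.0, abs=1e-3)
        assert curve.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_two_points_allowed_with_warning(self):
        with pytest.warns(UserWarning, match="two points"):
            curve = bm.fit_standard_curve([1, 0.01], [20, 26.6439])
        assert curve.r_squared == pytest.approx(1.0)

    def test_non_monotone_curve_warns_on_efficiency(self):
        with pytest.warns(UserWarning, match="efficiency out of range"):
            bm.fit_standard_curve([1, 0.1, 0.01], [20, 19, 21])


class TestQpcrCopyRatio:
    @pytest.mark.parametrize("copies", [1, 2, 3, 4, 5, 8, 12])
    def test_noiseless_ratio_exact_for_any_copy_count(self, copies):
        tab = bm.simulate_qpcr(copies, noise_sd=0.0)
        call = bm.qpcr_copy_ratio(tab, "S1")
        assert call.ratio == pytest.approx(copies / 2.0, abs=1e-9)

    def test_classes_from_noiseless_diplotypes(self):
        for copies, cls in [(2, "noncarrier"), (5, "het_carrier"), (8, "hom_carrier")]:
            call = bm.qpcr_copy_ratio(bm.simulate_qpcr(copies, noise_sd=0.0), "S1")
            assert call.genotype_class == cls

    def test_missing_standard_curve_errors(self):
        tab = bm.simulate_qpcr(4, noise_sd=0.0)
        with pytest.raises(ValueError, match="no standard curve"):
            bm.qpcr_copy_ratio(tab[tab["sample"] != "std"], "S1")


class TestJunctionCopies:
    def test_paper_worked_case_five_reads_cov_two(self):
        """S=5 at c=2 -> 3 junctions -> fourfold tandem unit."""
        assert bm.junction_copies(5, 2.0) == 4

    def test_no_split_reads_means_single_copy(self):
        assert bm.junction_copies(0, 2.0) == 1

    def test_round_half_up(self):
        assert bm.junction_copies(3, 2.0) == 3  # 1.5 -> 2 junctions

    def test_modal_estimate_recovers_fourfold(self):
        """k=4 at 20x per-junction coverage: modal estimate over 100
        Poisson replicates is 4."""
        rng = np.random.default_rng(6)
        ks = [bm.junction_copies(rng.poisson(20 * 3), 20.0) for _ in range(100)]
        vals, counts = np.unique(ks, return_counts=True)
        assert vals[np.argmax(counts)] == 4

    def test_invalid_coverage(self):
        with pytest.raises(ValueError):
            bm.junction_copies(5, 0.0)


def _tandem_reads(ref, left, right, n=6, side="right", read_len=80, offset=1):
    """Error-free junction-spanning reads for an array with boundaries
    (left, right), 1-based within ref at `offset`."""
    rows = []
    for i in range(n):
        aligned = 40 + i
        clip_len = read_len - aligned
        if side == "right":
            rows.append(
                (f"r{i}", right - aligned + 1, right, "right",
                 ref[left - offset : left - offset + clip_len])
            )
        else:
            rows.append(
                (f"r{i}", left, left + aligned - 1, "left",
                 ref[right - offset - clip_len + 1 : right - offset + 1])
            )
    return pd.DataFrame(rows, columns=["read_id", "mapped_start", "mapped_end", "clip_side", "clip_seq"])


class TestBreakpointsFromClips:
    def _ref(self, L=20000, seed=0):
        rng = np.random.default_rng(seed)
        return "".join(rng.choice(list("ACGT"), size=L))

    def test_planted_junction_recovered_exactly(self):
        ref = self._ref()
        reads = _tandem_reads(ref, 10_000, 15_770)
        bp = bm.breakpoints_from_clips(reads, ref, ref_offset=1)
        assert (bp.left, bp.right) == (10_000, 15_770)

    def test_left_side_clips_also_recover_junction(self):
        ref = self._ref(seed=2)
        reads = _tandem_reads(ref, 10_000, 15_770, side="left")
        bp = bm.breakpoints_from_clips(reads, ref, ref_offset=1)
        assert (bp.left, bp.right) == (10_000, 15_770)

    def test_exact_recovery_for_any_tandem_multiplicity(self):
        """Error-free reads from arrays with k = 2..6 all yield the planted
        boundaries (the count of reads varies, the consensus does not)."""
        ref = self._ref(seed=3)
        for k in range(2, 7):
            reads = _tandem_reads(ref, 8_000, 13_999, n=2 * (k - 1))
            bp = bm.breakpoints_from_clips(reads, ref)
            assert (bp.left, bp.right) == (8_000, 13_999)

    def test_discordant_endpoints_use_mode_then_smaller(self):
        ref = self._ref(seed=4)
        reads = _tandem_reads(ref, 10_000, 15_770, n=4)
        reads.loc[0, "mapped_end"] = 15_771  # one off-by-one record
        bp = bm.breakpoints_from_clips(reads, ref)
        assert bp.right == 15_770
        # exact tie -> smaller coordinate
        reads2 = _tandem_reads(ref, 10_000, 15_770, n=4)
        reads2.loc[[0, 1], "mapped_end"] = 15_771
        bp2 = bm.breakpoints_from_clips(reads2, ref)
        assert bp2.right == 15_770

    def test_single_read_is_insufficient(self):
        ref = self._ref()
        reads = _tandem_reads(ref, 10_000, 15_770, n=1)
        with pytest.raises(ValueError, match="insufficient support"):
            bm.breakpoints_from_clips(reads, ref)

    def test_unmatched_consensus_reports_it(self):
        ref = self._ref()
        reads = _tandem_reads(ref, 10_000, 15_770)
        reads["clip_seq"] = ["T" * 30] * len(reads)
        with pytest.raises(BreakpointUnresolvedError) as err:
            bm.breakpoints_from_clips(reads, ref)
        assert "T" * 30 in str(err.value)

    def test_ambiguous_column_truncates_consensus(self):
        ref = self._ref(seed=5)
        reads = _tandem_reads(ref, 10_000, 15_770, n=4)
        # corrupt base 20 of half the clips: 50/50 column < 60% majority
        clips = list(reads["clip_seq"])
        for i in (0, 1):
            s = clips[i]
            clips[i] = s[:19] + ("A" if s[19] != "A" else "C") + s[20:]
        reads["clip_seq"] = clips
        bp = bm.breakpoints_from_clips(reads, ref)
        assert len(bp.consensus) == 19
        assert (bp.left, bp.right) == (10_000, 15_770)


class TestFilterPrivateVariants:
    def _table(self):
        return pd.DataFrame(
            {
                "variant": ["v1", "v2", "v3"],
                "case1": [2, 2, 2],
                "case2": [2, 2, 2],
                "cross": [1, 1, 1],
                "ctrl1": [0, 1, 0],
                "ctrl2": [0, 0, 0],
            }
        )

    def test_qualifying_variant_kept(self):
        out = filter_private_variants(self._table(), ["case1", "case2"], ["cross"], ["ctrl1", "ctrl2"])
        assert set(out["variant"]) == {"v1", "v3"}

    def test_het_control_excludes_variant(self):
        out = filter_private_variants(self._table(), ["case1", "case2"], ["cross"], ["ctrl1", "ctrl2"])
        assert "v2" not in set(out["variant"])

    def test_planted_table_matches_recount_oracle(self):
        rng = np.random.default_rng(11)
        n = 300
        cols = {
            "case1": rng.integers(0, 3, n),
            "case2": rng.integers(0, 3, n),
            "cross": rng.integers(0, 3, n),
            "ctrl1": rng.integers(0, 3, n),
        }
        tab = pd.DataFrame({"variant": [f"v{i}" for i in range(n)], **cols})
        # plant exactly two qualifying rows
        for i in (17, 230):
            tab.loc[i, ["case1", "case2", "cross", "ctrl1"]] = [2, 2, 1, 0]
        # remove accidental qualifiers
        acc = (tab["case1"] == 2) & (tab["case2"] == 2) & (tab["cross"] == 1) & (tab["ctrl1"] == 0)
        for i in tab.index[acc]:
            if i not in (17, 230):
                tab.loc[i, "ctrl1"] = 1
        out = filter_private_variants(tab, ["case1", "case2"], ["cross"], ["ctrl1"])
        oracle = [
            r["variant"]
            for _, r in tab.iterrows()
            if r["case1"] == 2 and r["case2"] == 2 and r["cross"] == 1 and r["ctrl1"] == 0
        ]
        assert list(out["variant"]) == oracle == ["v17", "v230"]
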