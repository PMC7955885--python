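"""Windowed pi / Weir-Cockerham FST, quantile thresholds and sweep calling."""

import math

import numpy as np
import pandas as pd
import pytest

from napustools import sweeps, variants
from napustools.simulate import PopSimParams, simulate_populations
from napustools.sweeps import (
    DegenerateDistributionError,
    SweepRegion,
    call_sweeps,
    empirical_threshold,
    overlap_annotations,
    scan_windows,
    site_fst_components,
    site_pi,
)
from conftest import brute_force_pi


def _matrix_from_calls(calls, groups):
    """GenotypeMatrix with one chromosome and evenly spaced sites."""
    calls = np.asarray(calls, dtype=np.int8)
    n_samples = calls.shape[1] // 2
    samples = [f"s{i}" for i in range(n_samples)]
    return variants.GenotypeMatrix(
        chrom=np.array(["chr1"] * calls.shape[0]),
        pos=np.arange(1, calls.shape[0] + 1) * 100,
        ref=np.array(["A"] * calls.shape[0]),
        alt=np.array(["G"] * calls.shape[0]),
        calls=calls,
        samples=samples,
        sample_groups=dict(zip(samples, groups)),
    )


class TestWindowPi:
    def test_single_site_two_two_split(self):
        # 2 ref / 2 alt haploid calls: 4 of 6 pairs differ -> pi = 2/3
        pi = site_pi(np.array([[0, 0, 1, 1]], dtype=np.int8))
        assert pi[0] == pytest.approx(4 / 6, abs=1e-12)
        m = _matrix_from_calls([[0, 0, 1, 1]], ["A", "A"])
        df = scan_windows(m, "A", None, window=10_000, step=10_000,
                          chrom_lengths={"chr1": 10_000})
        assert df["pi_a"][0] == pytest.approx((4 / 6) / 10_000, abs=1e-12)

    def test_monomorphic_window_has_zero_pi(self):
        m = _matrix_from_calls([[1, 1, 1, 1]], ["A", "A"])
        df = scan_windows(m, "A", None, window=1000, step=1000,
                          chrom_lengths={"chr1": 1000})
        assert df["pi_a"][0] == 0.0

    def test_matches_all_pairs_hamming_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            calls = rng.integers(0, 2, size=(12, 8)).astype(np.int8)
            calls[rng.random(calls.shape) < 0.1] = -1
            m = _matrix_from_calls(calls, ["A"] * 4)
            df = scan_windows(m, "A", None, window=2000, step=2000,
                              chrom_lengths={"chr1": 2000})
            assert df["pi_a"][0] * 2000 == pytest.approx(
                brute_force_pi(calls), abs=1e-12
            )

    def test_site_with_fewer_than_two_calls_skipped(self):
        pi = site_pi(np.array([[1, -1, -1, -1]], dtype=np.int8))
        assert pi[0] == 0.0


class TestWindowFst:
    def test_fixed_difference_gives_fst_one(self):
        gt_a = np.ones((1, 10, 2), dtype=np.int8)
        gt_b = np.zeros((1, 10, 2), dtype=np.int8)
        a, b, c = site_fst_components(gt_a, gt_b)
        assert a[0] / (a + b + c)[0] == pytest.approx(1.0, abs=1e-12)

    def test_symmetric_half_frequency_case(self):
        # both pops 5 hom-ref + 5 hom-alt, no hets: hand evaluation gives
        # a = -0.25/9, b = (10/9)*0.25, c = 0 -> FST = -1/9
        g = np.array([[[0, 0]] * 5 + [[1, 1]] * 5], dtype=np.int8)
        a, b, c = site_fst_components(g, g.copy())
        assert a[0] == pytest.approx(-0.25 / 9, abs=1e-12)
        assert b[0] == pytest.approx(10 / 9 * 0.25, abs=1e-12)
        assert c[0] == pytest.approx(0.0, abs=1e-12)
        assert a[0] / (a + b + c)[0] == pytest.approx(-1 / 9, abs=1e-12)

    def test_label_permutation_centres_fst_near_zero(self):
        """Permuting group labels on null data centres windowed FST near 0."""
        rng = np.random.default_rng(23)
        n_sites, n_dip = 60, 20
        p = rng.uniform(0.1, 0.9, n_sites)
        calls = (rng.random((n_sites, 2 * n_dip)) < p[:, None]).astype(np.int8)
        fsts = []
        for _ in range(200):
            labels = np.array(["A"] * 10 + ["B"] * 10)
            rng.shuffle(labels)
            m = _matrix_from_calls(calls, labels)
            df = scan_windows(m, "A", "B", window=6100, step=6100,
                              chrom_lengths={"chr1": 6100})
            fsts.append(df["fst"][0])
        assert abs(np.mean(fsts)) < 0.02

    def test_missing_group_is_configuration_error(self):
        m = _matrix_from_calls([[0, 1, 0, 1]], ["A", "A"])
        with pytest.raises(variants.GroupMapError):
            scan_windows(m, "A", "Z", window=1000, step=1000)


class TestEmpiricalThreshold:
    def test_upper_tail_on_distinct_values(self):
        thr, idx = empirical_threshold(np.arange(1, 101), "upper", 0.05)
        assert thr == 96 and sorted(np.arange(1, 101)[idx]) == [96, 97, 98, 99, 100]

    def test_lower_tail_symmetry(self):
        thr, idx = empirical_threshold(np.arange(1, 101), "lower", 0.05)
        assert thr == 5 and sorted(np.arange(1, 101)[idx]) == [1, 2, 3, 4, 5]

    def test_q_one_retains_everything(self):
        _, idx = empirical_threshold(np.arange(1, 101), "upper", 1.0)
        assert len(idx) == 100

    def test_ties_kept_together(self):
        # twenty 1s and five 2s at q=0.2 (k=5): the five 2s are the tail
        vals = np.array([1.0] * 20 + [2.0] * 5)
        thr, idx = empirical_threshold(vals, "upper", 0.2)
        assert thr == 2.0 and len(idx) == 5

    def test_degenerate_distribution_rejected(self):
        with pytest.raises(DegenerateDistributionError):
            empirical_threshold(np.ones(50), "upper", 0.05)


def _stats_frame(fst, ratio, window=10_000):
    n = len(fst)
    return pd.DataFrame({
        "chrom": ["chr1"] * n,
        "start": np.arange(n) * window,
        "end": (np.arange(n) + 1) * window,
        "pi_a": 1e-4, "pi_b": 1e-4,
        "pi_ratio": ratio, "fst": fst,
        "n_snps": 10, "partial": False,
    })


class TestCallSweeps:
    def test_joint_filter_and_merge_of_adjacent_windows(self):
        # windows 48 and 49 are jointly extreme (high FST, low ratio) for
        # group A; the remaining tail members of each marginal do not
        # co-occur, so the two adjacent windows merge into a single region
        fst = np.concatenate([[0.5], np.linspace(0.0, 0.2, 47), [0.9, 0.9]])
        ratio = np.concatenate([[1.0, 0.5, 2.0, 2.1, 2.2],
                                np.full(43, 1.0) + np.linspace(-0.02, 0.02, 43),
                                [0.01, 0.01]])
        regions = call_sweeps(_stats_frame(fst, ratio), "A", "B")
        assert len(regions) == 1
        r = regions[0]
        assert (r.start, r.end, r.selected_group, r.n_windows) == (480_000, 500_000, "A", 2)

    def test_upper_ratio_tail_selects_denominator_group(self):
        fst = np.concatenate([np.linspace(0.0, 0.2, 49), [0.9]])
        ratio = np.concatenate([np.linspace(0.8, 1.2, 49), [50.0]])
        regions = call_sweeps(_stats_frame(fst, ratio), "A", "B")
        assert [r.selected_group for r in regions] == ["B"]

    def test_no_window_passing_both_filters_gives_empty_list(self):
        # FST tail (windows 0-2) and both ratio tails (windows 10-12 and
        # 20-22) fall on disjoint windows, so the joint filter is empty
        fst = np.concatenate([[0.9, 0.85, 0.8], np.linspace(0.0, 0.2, 47)])
        ratio = np.full(50, 1.0) + np.linspace(-0.02, 0.02, 50)
        ratio[10:13] = 0.01
        ratio[20:23] = 3.0
        assert call_sweeps(_stats_frame(fst, ratio), "A", "B") == []

    def test_planted_sweep_recovered_from_generator_truth(self, pop_run):
        params, paths = pop_run
        m = variants.load_genotypes(paths["vcf"], str(paths["groups"]))
        stats = scan_windows(m, "G0", "G1", window=params.window_len,
                             step=params.window_len,
                             chrom_lengths={"chr1": params.chrom_len})
        # planted window has the top FST rank
        assert stats["fst"].idxmax() == 10
        regions = call_sweeps(stats, "G0", "G1")
        assert any(
            r.selected_group == "G0" and r.start <= 10 * params.window_len
            and r.end >= 11 * params.window_len
            for r in regions
        )


class TestOverlapAnnotations:
    def _region(self, start, end):
        return SweepRegion("chr1", start, end, "A", 1, 0.5, 0.1)

    def test_one_bp_overlap_counts(self, tmp_path):
        gff = tmp_path / "g.gff3"
        gff.write_text("##gff-version 3\nchr1\t.\tgene\t5000\t8000\t.\t+\t.\tID=g1\n")
        regions = overlap_annotations([self._region(1000, 5000)], gff3=str(gff))
        assert regions[0].genes == ["g1"]  # gene starts at base 5000 (1-based)

    def test_half_open_boundary_does_not_overlap(self, tmp_path):
        gff = tmp_path / "g.gff3"
        gff.write_text("##gff-version 3\nchr1\t.\tgene\t5001\t8000\t.\t+\t.\tID=g1\n")
        regions = overlap_annotations([self._region(1000, 5000)], gff3=str(gff))
        assert regions[0].genes == []

    def test_chromosome_mismatch_is_reconciliation_error(self, tmp_path):
        gff = tmp_path / "g.gff3"
        gff.write_text("##gff-version 3\nchr2\t.\tgene\t1\t10\t.\t+\t.\tID=g1\n")
        with pytest.raises(ValueError, match="chr1"):
            overlap_annotations([self._region(0, 100)], gff3=str(gff))

    def test_planted_nlrs_inside_sweep_region_are_reported(self, tmp_path):
        gff = tmp_path / "g.gff3"
        rows = [f"chr1\t.\tgene\t{s}\t{s + 999}\t.\t+\t.\tID=n{i}"
                for i, s in enumerate((2000, 4000, 6000, 50_000))]
        gff.write_text("##gff-version 3\n" + "\n".join(rows) + "\n")
        regions = overlap_annotations(
            [self._region(1000, 10_000)], gff3=str(gff), nlr_ids={"n0", "n1", "n2", "n3"}
        )
        assert regions[0].nlr_ids == ["n0", "n1", "n2"]
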