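"""LTR divergence, insertion dating, age profiles, enrichment, flank test."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from napustools import ltr
from napustools.ltr import (
    AlignmentError,
    SaturationError,
    age_group,
    age_profile,
    centromere_enrichment,
    flank_presence_test,
    insertion_age,
    ltr_divergence,
)


class TestDivergence:
    def test_identical_sequences_have_zero_distance(self):
        seq = "ACGT" * 125
        p, K, aligned, mism = ltr_divergence(seq, seq)
        assert (p, K, mism) == (0.0, 0.0, 0) and aligned == 500

    def test_jc69_closed_form_at_two_percent(self):
        seq5 = "A" * 500
        seq3 = "A" * 490 + "C" * 10
        p, K, aligned, mism = ltr_divergence(seq5, seq3)
        assert (aligned, mism) == (500, 10)
        assert p == pytest.approx(0.02, abs=1e-12)
        assert K == pytest.approx(-0.75 * math.log(1 - 0.08 / 3), abs=1e-12)

    def test_raw_correction_returns_p(self):
        _, K, _, _ = ltr_divergence("A" * 500, "A" * 490 + "C" * 10, correction="raw")
        assert K == pytest.approx(0.02, abs=1e-12)

    def test_gap_columns_excluded(self):
        rng = np.random.default_rng(1)
        s = "".join(rng.choice(list("ACGT"), 500))
        s_ins = s[:200] + "TTT" + s[200:]
        p, K, aligned, mism = ltr_divergence(s, s_ins)
        assert p == 0.0 and mism == 0 and aligned == 500

    def test_saturation_raises(self):
        with pytest.raises(SaturationError):
            ltr_divergence("A" * 100, "C" * 100)

    def test_empty_sequence_rejected(self):
        with pytest.raises(AlignmentError):
            ltr_divergence("", "ACGT")


class TestInsertionAge:
    def test_zero_distance_is_age_zero_youngest_group(self):
        assert insertion_age(0.0) == (0.0, "<0.2My")

    def test_ten_thousand_year_boundary(self):
        # K = 2.8e-4 at the published rate dates to exactly 10,000 years
        T, group = insertion_age(2.8e-4, 1.4e-8)
        assert T == pytest.approx(10_000.0, rel=1e-12)
        assert group == "<0.2My"

    def test_mid_range_age_and_group(self):
        T, group = insertion_age(0.020272, 1.4e-8)
        assert T == pytest.approx(0.020272 / 2.8e-8, rel=1e-12)
        assert group == "0.2-1My"

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            insertion_age(-0.1)

    @pytest.mark.parametrize(
        "t,grp",
        [(0, "<0.2My"), (199_999, "<0.2My"), (200_000, "0.2-1My"),
         (1_000_000, "0.2-1My"), (1_000_001, ">1My")],
    )
    def test_age_groups_partition_the_axis(self, t, grp):
        assert age_group(t) == grp

    @given(st.floats(min_value=0, max_value=0.5), st.floats(min_value=1e-9, max_value=1e-7))
    @settings(max_examples=50, deadline=None)
    def test_age_is_monotone_in_distance(self, k, r):
        t1, _ = insertion_age(k, r)
        t2, _ = insertion_age(k + 1e-6, r)
        assert t2 > t1

    @given(st.integers(min_value=0, max_value=25))
    @settings(max_examples=26, deadline=None)
    def test_jc69_agrees_with_p_to_first_order(self, mism):
        p, K, _, _ = ltr_divergence("A" * 500, "A" * (500 - mism) + "C" * mism)
        assert abs(K - p) <= p**2 + 1e-12


class TestAgeProfile:
    def test_counts_conserved_within_ranges(self):
        hists = age_profile([0.0, 5e3, 4.9e6])
        assert hists["young"]["count"].sum() == 2
        assert hists["old"]["count"].sum() == 3

    def test_empty_input_gives_all_zero_bins(self):
        hists = age_profile([])
        assert hists["young"]["count"].sum() == 0
        assert len(hists["young"]) == 50 and len(hists["old"]) == 50

    def test_uniform_cohort_fits_uniform_histogram(self):
        """Chi-square GOF to uniform is not rejected at alpha=0.01 (20 seeds)."""
        from scipy import stats as sps

        rejections = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            ages = rng.uniform(0, 5e5, 2000)
            counts = age_profile(ages)["young"]["count"].to_numpy()
            _, pval = sps.chisquare(counts)
            rejections += pval < 0.01
        assert rejections <= 2


class TestCentromereEnrichment:
    def _elements(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "age_group"])

    def test_fraction_from_midpoints(self, tmp_path):
        bed = tmp_path / "cen.bed"
        bed.write_text("chr1\t1000\t2000\n")
        rows = [("chr1", 1100, 1200, "<0.2My")] * 4 + [("chr1", 5000, 5100, "<0.2My")] * 6
        table, _ = centromere_enrichment(self._elements(rows), bed)
        young = table[table["age_group"] == "<0.2My"].iloc[0]
        assert young["fraction"] == pytest.approx(0.4)

    def test_empty_centromere_bed_gives_zero_fractions(self, tmp_path):
        bed = tmp_path / "cen.bed"
        bed.write_text("")
        rows = [("chr1", 0, 100, g) for g in ("<0.2My", "0.2-1My", ">1My")]
        table, p = centromere_enrichment(self._elements(rows), bed)
        assert (table["fraction"] == 0).all()

    def test_planted_placement_probabilities_recovered(self, tmp_path):
        """Generator probabilities (0.45, 0.29, 0.26) recovered within +/-0.04."""
        from napustools.simulate import LTRSimParams, simulate_ltr_elements

        params = LTRSimParams(
            n_elements=2000, ltr_len=50, internal_len=50,
            ages=(1e4, 5e5, 2e6),
            centromere_placement_prob_by_age_group=(0.45, 0.29, 0.26),
            seed=12,
        )
        paths = simulate_ltr_elements(params, tmp_path)
        truth = pd.read_csv(paths["truth"], sep="\t")
        bed = pd.read_csv(paths["placements"], sep="\t", header=None,
                          names=["chrom", "start", "end", "id"])
        df = bed.merge(truth[["id", "age_years"]], on="id")
        df["age_group"] = df["age_years"].map(age_group)
        table, pval = centromere_enrichment(df, paths["centromere_bed"])
        planted = dict(zip(ltr.AGE_GROUPS, params.centromere_placement_prob_by_age_group))
        for row in table.itertuples():
            assert abs(row.fraction - planted[row.age_group]) <= 0.04
        assert pval < 0.01  # young vs older difference is detectable


class TestFlankPresence:
    def _fixture(self, seed=0):
        rng = np.random.default_rng(seed)
        left = "".join(rng.choice(list("ACGT"), 1500))
        right = "".join(rng.choice(list("ACGT"), 1500))
        element = "".join(rng.choice(list("ACGT"), 3000))
        return left, element, right

    def test_identical_genome_reports_present(self):
        left, element, right = self._fixture()
        genome = left + element + right
        assert flank_presence_test(element, left, right, genome) == "present"

    def test_deleted_site_reports_absent_specific(self):
        left, element, right = self._fixture(1)
        genome = left + right  # element excised
        assert flank_presence_test(element, left, right, genome) == "absent_specific"

    def test_repetitive_flank_is_unresolved(self):
        left, element, right = self._fixture(2)
        genome = (left + element + right) * 50
        assert flank_presence_test(element, left, right, genome) == "unresolved"

    def test_short_flank_rejected(self):
        left, element, right = self._fixture(3)
        with pytest.raises(ValueError):
            flank_presence_test(element, left[:500], right, left + right)


class TestAgeRecovery:
    def test_mean_estimated_age_within_ten_percent(self, tmp_path):
        """Simulated cohorts dated within 10% of truth (full-size cohorts,
        including the noisier 1e4-year age, run in the acceptance suite)."""
        import pyfaidx

        from napustools.simulate import LTRSimParams, simulate_ltr_elements

        for age in (1e5, 1e6):
            params = LTRSimParams(
                n_elements=120, ltr_len=2000, internal_len=100, ages=(age,), seed=31
            )
            paths = simulate_ltr_elements(params, tmp_path / f"a{age:.0f}")
            fa = pyfaidx.Fasta(str(paths["fasta"]))
            elements = ltr.load_elements(paths["truth"], fa)
            ltr.date_elements(elements)
            mean_t = np.mean([e.T for e in elements])
            assert abs(mean_t - age) / age <= 0.10
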