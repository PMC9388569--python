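"""Somatic-variant filtering: support/VAF thresholds, the cross-patient
chi-squared artifact test, and germline blacklist exclusion."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2_contingency

from gliomics.simulate import SimulationConfig, simulate_paired_cohort
from gliomics.variants import (
    artifact_chisq,
    cohort_variant_counts,
    filter_artifacts,
    filter_by_support,
    filter_germline,
    load_blacklist,
    read_vcf,
    write_vcf,
)


def _calls(rows):
    df = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "alt_reads", "ref_reads"])
    df["sample_id"] = "s1"
    df["patient_id"] = "p1"
    df["timepoint"] = "primary"
    df["vaf"] = df["alt_reads"] / (df["alt_reads"] + df["ref_reads"])
    return df


class TestSupportFilter:
    @pytest.mark.parametrize(
        "alt,ref,kept",
        [
            (2, 2, False),   # VAF 0.5 but only 2 supporting reads
            (3, 27, True),   # both boundaries exactly met: 3 reads, VAF 0.10
            (3, 28, False),  # VAF just below 10%
            (0, 50, False),  # no support at all
            (3, 0, True),    # VAF 1.0
            (6, 55, False),  # 6 reads but VAF < 0.10
            (6, 54, True),   # VAF exactly 0.10
        ],
    )
    def test_boundaries_inclusive(self, alt, ref, kept):
        calls = _calls([("chr1", 100, "A", "T", alt, ref)])
        out = filter_by_support(calls)
        assert (len(out) == 1) == kept

    def test_order_preserved_and_empty(self):
        calls = _calls([("chr1", i, "A", "T", 10, 10) for i in (5, 3, 9)])
        out = filter_by_support(calls)
        assert list(out["pos"]) == [5, 3, 9]
        assert filter_by_support(calls.iloc[0:0]).empty

    def test_commutes_with_germline_filter(self):
        rng = np.random.default_rng(0)
        rows = [
            ("chr1", int(p), "A", "T", int(a), int(r))
            for p, a, r in zip(rng.integers(1, 500, 40), rng.integers(0, 10, 40), rng.integers(1, 60, 40))
        ]
        calls = _calls(rows)
        blacklist = {("chr1", int(p), "A", "T") for p in rng.integers(1, 500, 15)}
        ab = filter_germline(filter_by_support(calls), blacklist)
        ba = filter_by_support(filter_germline(calls, blacklist))
        pd.testing.assert_frame_equal(ab.reset_index(drop=True), ba.reset_index(drop=True))


class TestArtifactChisq:
    def test_identical_fractions_give_null(self):
        stat, p, dof = artifact_chisq([10, 10], [100, 100])
        assert stat == 0.0 and p == 1.0 and dof == 1

    def test_many_identical_patients_still_null(self):
        for n_pat in (3, 5, 8):
            stat, p, dof = artifact_chisq([7] * n_pat, [40] * n_pat)
            assert stat == pytest.approx(0.0) and p == pytest.approx(1.0)
            assert dof == n_pat - 1

    def test_two_patient_contrast_matches_contingency_oracle(self):
        # patients (40/50) and (0/50): strongly heterogeneous
        stat, p, dof = artifact_chisq([40, 0], [50, 50])
        table = np.array([[40, 10], [0, 50]])
        oracle = chi2_contingency(table, correction=False)
        assert stat == pytest.approx(66.6667, abs=1e-3)
        assert stat == pytest.approx(oracle.statistic, rel=1e-12)
        assert p == pytest.approx(oracle.pvalue, rel=1e-9)
        assert dof == 1

    def test_random_tables_match_contingency_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            n_pat = rng.integers(2, 6)
            total = rng.integers(1, 201, size=n_pat)
            alt = np.array([rng.integers(0, t + 1) for t in total])
            stat, p, dof = artifact_chisq(alt, total)
            ref = total - alt
            if alt.sum() == 0 or ref.sum() == 0:
                assert stat == 0.0 and p == 1.0
                continue
            oracle = chi2_contingency(np.column_stack([alt, ref]), correction=False)
            assert stat == pytest.approx(float(oracle.statistic), abs=1e-9)
            assert p == pytest.approx(float(oracle.pvalue), abs=1e-9)
            assert dof == n_pat - 1

    def test_degenerate_margins(self):
        assert artifact_chisq([0, 0], [50, 60]) == (0.0, 1.0, 1)
        assert artifact_chisq([50, 60], [50, 60]) == (0.0, 1.0, 1)

    def test_zero_total_patients_excluded_and_minimum_enforced(self):
        stat, p, dof = artifact_chisq([10, 0, 5], [100, 0, 50])
        assert dof == 1  # the empty patient dropped
        with pytest.raises(ValueError, match="fewer than 2"):
            artifact_chisq([10, 0], [100, 0])


class TestFilterArtifacts:
    def test_homogeneous_variant_removed_heterogeneous_kept(self):
        calls = _calls([("chr1", 100, "A", "T", 30, 30), ("chr1", 200, "C", "G", 25, 35)])
        counts = pd.DataFrame(
            {
                "chrom": ["chr1"] * 4,
                "pos": [100, 100, 200, 200],
                "ref": ["A", "A", "C", "C"],
                "alt": ["T", "T", "G", "G"],
                "patient_id": ["p1", "p2", "p1", "p2"],
                "alt_sum": [30, 31, 25, 0],
                "total_sum": [60, 60, 60, 60],
            }
        )
        out, audit = filter_artifacts(calls, counts, alpha=0.01)
        assert list(out["pos"]) == [200]
        decisions = dict(zip(audit["variant"], audit["decision"]))
        assert decisions["chr1:100:A>T"] == "removed_artifact"
        assert decisions["chr1:200:C>G"] == "retained"

    def test_missing_key_names_the_variant(self):
        calls = _calls([("chr1", 123, "A", "T", 10, 10)])
        counts = pd.DataFrame(
            {"chrom": ["chr2"], "pos": [5], "ref": ["A"], "alt": ["T"], "patient_id": ["p1"],
             "alt_sum": [1], "total_sum": [10]}
        )
        with pytest.raises(KeyError, match="chr1:123 A>T"):
            filter_artifacts(calls, counts, alpha=0.01)

    def test_alpha_monotonicity(self):
        rng = np.random.default_rng(5)
        calls = _calls([("chr1", int(i), "A", "T", 20, 20) for i in range(1, 31)])
        rows = []
        for i in range(1, 31):
            for pid in ("p1", "p2", "p3"):
                tot = int(rng.integers(30, 90))
                rows.append({"chrom": "chr1", "pos": i, "ref": "A", "alt": "T", "patient_id": pid,
                             "alt_sum": int(rng.integers(0, tot + 1)), "total_sum": tot})
        counts = pd.DataFrame(rows)
        kept_sets = []
        for alpha in (0.001, 0.01, 0.05, 0.2):
            out, _ = filter_artifacts(calls, counts, alpha=alpha)
            kept_sets.append(set(out["pos"]))
        for small, big in zip(kept_sets, kept_sets[1:]):
            assert small <= big  # raising alpha never removes a retained call

    def test_planted_artifacts_removed_true_somatic_retained(self, bundle):
        sup = filter_by_support(bundle.variants)
        out, _ = filter_artifacts(sup, bundle.cohort_counts, alpha=0.01)
        artifacts_in = (sup["truth"] == "artifact").sum()
        artifacts_out = (out["truth"] == "artifact").sum()
        assert artifacts_in > 0
        assert 1 - artifacts_out / artifacts_in >= 0.95
        somatic_in = (sup["truth"] == "somatic").sum()
        somatic_out = (out["truth"] == "somatic").sum()
        assert somatic_out / somatic_in >= 0.99

    def test_no_artifacts_config_retains_all_true_calls(self):
        b = simulate_paired_cohort(
            SimulationConfig(seed=3, n_patients=3, n_artifacts=0, n_germline=0,
                             n_true_somatic=25, hypermutator_patient=None)
        )
        sup = filter_by_support(b.variants)
        for alpha in (0.001, 0.05):
            out, _ = filter_artifacts(sup, b.cohort_counts, alpha=alpha)
            assert len(out) == len(sup)


class TestGermlineFilter:
    def test_allele_exact_matching(self):
        calls = _calls([("chr1", 100, "A", "T", 10, 10), ("chr1", 100, "A", "G", 10, 10)])
        out = filter_germline(calls, {("chr1", 100, "A", "T")})
        assert list(out["alt"]) == ["G"]  # same position, different alt retained

    def test_empty_blacklist_is_identity(self):
        calls = _calls([("chr1", 100, "A", "T", 10, 10)])
        pd.testing.assert_frame_equal(filter_germline(calls, set()), calls)

    def test_blacklist_loader_and_errors(self, tmp_path):
        p = tmp_path / "bl.vcf"
        p.write_text(
            "##fileformat=VCFv4.2\n#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "chr1\t100\t.\tA\tT,G\t.\tPASS\t.\n"
            "chr2\t7\trs1\tC\tG\t.\tPASS\t.\n"
        )
        bl = load_blacklist(p)
        assert bl == {("chr1", 100, "A", "T"), ("chr1", 100, "A", "G"), ("chr2", 7, "C", "G")}
        bad = tmp_path / "bad.vcf"
        bad.write_text("chr1\t100\t.\tA\tT\n\nchr1\tbroken\n")
        with pytest.raises(ValueError, match="line 3"):
            load_blacklist(bad)

    def test_germline_leaks_removed_from_bundle(self, bundle):
        sup = filter_by_support(bundle.variants)
        retained, _ = filter_artifacts(sup, bundle.cohort_counts, alpha=0.01)
        final = filter_germline(retained, bundle.blacklist)
        assert (retained["truth"] == "germline").sum() > 0
        assert (final["truth"] == "germline").sum() == 0
        assert (final["truth"] == "somatic").sum() == (retained["truth"] == "somatic").sum()


def test_vcf_round_trip(tmp_path, bundle):
    sub = bundle.variants[bundle.variants["sample_id"] == "case1-primary"].head(20)
    p = tmp_path / "case1.vcf"
    write_vcf(sub, p)
    back = read_vcf(p, patient_id="case1", timepoint="primary")
    for col in ("chrom", "pos", "ref", "alt", "alt_reads", "ref_reads"):
        assert list(back[col]) == list(sub[col])
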