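"""Quality control: marker statistics, filter thresholds (including the
strict/non-strict boundaries), contemporary groups, phenotype filters."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pleionet import qc, simulate
from pleionet.datatypes import GenotypeMatrix, SnpMap


def make_geno(columns: list[list[int]]) -> GenotypeMatrix:
    """Build a genotype matrix from per-SNP dosage columns."""
    arr = np.array(columns, dtype=np.int8).T
    n_snp = arr.shape[1]
    smap = SnpMap(
        np.array([f"s{j}" for j in range(n_snp)], dtype=object),
        np.ones(n_snp, dtype=int),
        np.arange(1, n_snp + 1) * 100,
    )
    ids = np.array([f"a{i}" for i in range(arr.shape[0])], dtype=object)
    return GenotypeMatrix(ids, smap, arr)


class TestMarkerStatistics:
    def test_monomorphic_column(self):
        stats = qc.marker_statistics(make_geno([[0, 0, 0, 0]]))
        assert stats.loc[0, "maf"] == 0.0
        assert bool(stats.loc[0, "monomorphic"])

    def test_hand_counts(self):
        # dosages [0,1,1,2]: p=0.5, maf 0.5, het_obs 0.5, het_exp 0.5
        stats = qc.marker_statistics(make_geno([[0, 1, 1, 2]]))
        row = stats.iloc[0]
        assert row["freq_alt"] == 0.5
        assert row["maf"] == 0.5
        assert row["het_obs"] == 0.5
        assert row["het_exp"] == 0.5
        assert row["hwe_dev"] == 0.0

    def test_all_heterozygote_deviation(self):
        stats = qc.marker_statistics(make_geno([[1, 1, 1, 1]]))
        row = stats.iloc[0]
        assert row["het_obs"] == 1.0
        assert row["het_exp"] == 0.5
        assert row["hwe_dev"] == 0.5

    def test_zero_call_snp_flagged(self):
        stats = qc.marker_statistics(make_geno([[-1, -1, -1, -1]]))
        assert stats.loc[0, "call_rate"] == 0.0
        assert bool(stats.loc[0, "monomorphic"])


class TestFilterMarkers:
    def test_call_rate_below_threshold_removed(self):
        # 20 animals, 3 missing -> rate 0.85 < 0.90
        col = [0, 1] * 8 + [2] + [-1, -1, -1]
        geno = make_geno([col, [0, 1] * 10])
        kept, report = qc.filter_markers(geno)
        assert report.removed_by["call_rate"] == 1
        assert kept.n_snps == 1

    def test_maf_boundary_is_strict(self):
        # maf exactly 0.05 with 20 animals: 2 alt alleles / 40
        col = [1, 1] + [0] * 18
        geno = make_geno([col])
        kept, report = qc.filter_markers(geno)
        assert kept.n_snps == 1  # retained: strict <
        col_low = [1] + [0] * 19  # maf 0.025
        _, report2 = qc.filter_markers(make_geno([col_low, col]))
        assert report2.removed_by["maf"] == 1

    def test_hwe_deviation_above_threshold_removed(self):
        # all-het SNP: deviation 0.5 > 0.15
        het = [1] * 20
        ok = [0, 1, 1, 2] * 5
        _, report = qc.filter_markers(make_geno([het, ok]))
        assert report.removed_by["hwe_deviation"] == 1
        assert report.n_kept == 1

    def test_manifest_recovered_exactly(self, small_study):
        geno = small_study[0]
        clean, _ = qc.filter_markers(geno)  # start from a passing panel
        bad, manifest = simulate.inject_artifacts(
            clean, n_monomorphic=3, n_low_maf=2, seed=11
        )
        _, report = qc.filter_markers(bad)
        removed = {sid for ids in report.removed_ids.values() for sid in ids}
        expected = set(manifest["monomorphic"]) | set(manifest["low_maf"])
        assert removed == expected

    def test_counts_conserved_and_attribution_unique(self, small_study):
        geno = small_study[0]
        _, report = qc.filter_markers(geno)
        assert report.n_kept + report.n_removed == geno.n_snps
        all_ids = [sid for ids in report.removed_ids.values() for sid in ids]
        assert len(all_ids) == len(set(all_ids))


class TestFilterSamples:
    def test_fully_observed_keeps_all(self, small_study):
        geno = small_study[0]
        kept, report = qc.filter_samples(geno)
        assert kept.n_samples == geno.n_samples
        assert report.n_removed == 0

    def test_half_missing_sample_removed(self):
        arr = np.zeros((4, 10), dtype=np.int8)
        arr[1, :5] = -1  # 50% missing
        arr[:, 1] = 1
        geno = GenotypeMatrix(
            np.array(["a", "b", "c", "d"], dtype=object),
            SnpMap(
                np.array([f"s{j}" for j in range(10)], dtype=object),
                np.ones(10, int),
                np.arange(1, 11),
            ),
            arr,
        )
        kept, report = qc.filter_samples(geno)
        assert list(kept.sample_ids) == ["a", "c", "d"]
        assert report.removed_ids["sample_call_rate"] == ["b"]

    def test_matches_brute_force(self, rng):
        arr = rng.integers(0, 3, size=(100, 200)).astype(np.int8)
        miss = rng.random((100, 200)) < rng.uniform(0, 0.25, size=(100, 1))
        arr[miss] = -1
        geno = GenotypeMatrix(
            np.array([f"a{i}" for i in range(100)], dtype=object),
            SnpMap(
                np.array([f"s{j}" for j in range(200)], dtype=object),
                np.ones(200, int),
                np.arange(1, 201),
            ),
            arr,
        )
        kept, _ = qc.filter_samples(geno, 0.9)
        expected = [
            f"a{i}" for i in range(100) if np.sum(arr[i] != -1) / 200 >= 0.9
        ]
        assert list(kept.sample_ids) == expected

    def test_idempotent(self, small_study):
        geno = small_study[0]
        once, _ = qc.filter_samples(geno)
        twice, rep = qc.filter_samples(once)
        assert rep.n_removed == 0
        # call-rate and monomorphic marker filters are idempotent too
        mk_once, _ = qc.filter_markers(geno)
        _, rep2 = qc.filter_markers(mk_once)
        assert rep2.removed_by["call_rate"] == 0
        assert rep2.removed_by["monomorphic"] == 0


def toy_pheno(**overrides) -> pd.DataFrame:
    n = overrides.pop("n", 12)
    base = {
        "animal_id": [f"x{i}" for i in range(n)],
        "adg": np.linspace(0.5, 0.7, n),
        "wbsf": np.linspace(5, 7, n),
        "birth_year": [2010] * n,
        "birth_month": [3] * n,
        "herd_birth": ["H1"] * n,
        "herd_weaning": ["H1"] * n,
        "herd_yearling": ["H1"] * n,
        "slaughter_date": ["2012-05-01"] * n,
    }
    base.update(overrides)
    return pd.DataFrame(base)


class TestContemporaryGroups:
    def test_season_assignment(self):
        assert qc.birth_season(np.array([3]))[0] == "FebJul"
        assert list(qc.birth_season(np.array([8, 1, 7, 2]))) == [
            "AugJan",
            "AugJan",
            "FebJul",
            "FebJul",
        ]

    def test_identical_fields_share_label(self):
        pheno, _ = qc.build_contemporary_groups(toy_pheno())
        assert pheno["cg_adg"].nunique() == 1
        assert pheno["cg_wbsf"].nunique() == 1

    def test_groups_match_brute_force(self):
        pheno = toy_pheno(
            birth_year=[2010] * 6 + [2011] * 6,
            birth_month=[3] * 3 + [9] * 3 + [3] * 3 + [9] * 3,
        )
        out, _ = qc.build_contemporary_groups(pheno)
        assert out["cg_adg"].nunique() == 4
        brute = {}
        for i, row in pheno.iterrows():
            season = "AugJan" if row.birth_month in {8, 9, 10, 11, 12, 1} else "FebJul"
            key = (row.birth_year, season, row.herd_birth, row.herd_weaning, row.herd_yearling)
            brute.setdefault(key, []).append(i)
        ours = {lbl: list(grp.index) for lbl, grp in out.groupby("cg_adg")}
        assert sorted(map(sorted, brute.values())) == sorted(map(sorted, ours.values()))

    def test_missing_cg_field_invalidates_record(self):
        pheno = toy_pheno()
        pheno.loc[0, "herd_weaning"] = None
        pheno.loc[1, "slaughter_date"] = None
        out, report = qc.build_contemporary_groups(pheno)
        assert np.isnan(out.loc[0, "adg"]) and np.isnan(out.loc[0, "wbsf"])
        assert np.isnan(out.loc[1, "wbsf"]) and not np.isnan(out.loc[1, "adg"])
        assert report.removed_by["missing_cg_fields_adg"] == 1
        assert report.removed_by["missing_cg_fields_wbsf"] == 2


class TestFilterPhenotypes:
    def test_small_cg_dropped_entirely(self):
        pheno, _ = qc.build_contemporary_groups(toy_pheno(n=4))
        out, report = qc.filter_phenotypes(pheno)
        assert out["adg"].isna().all()
        assert report.removed_by["adg_small_cg"] == 4

    def test_boundary_exactly_3_5_sd_retained(self):
        # CG values [3.5, 0 x7, -0.5 x7]: mean 0 and sample SD exactly 1
        # (all representable in binary), so 3.5 sits exactly at 3.5 SD and
        # must survive the strict "more than" rule
        vals = [3.5] + [0.0] * 7 + [-0.5] * 7
        assert np.mean(vals) == 0.0 and np.std(vals, ddof=1) == 1.0
        pheno = toy_pheno(n=15, adg=vals, wbsf=[6.0] * 15)
        pheno, _ = qc.build_contemporary_groups(pheno)
        out, report = qc.filter_phenotypes(pheno)
        assert report.removed_by["adg_outlier_3.5sd"] == 0
        assert out["adg"].notna().all()

    def test_outlier_decision_matches_hand_computation(self):
        # with mean/SD computed including the candidate, {10 x5, 60} is NOT
        # beyond 3.5 SD (a lone outlier among 5 peers caps at z = 5/sqrt(6))
        vals = [10.0, 10, 10, 10, 10, 60]
        mean, sd = np.mean(vals), np.std(vals, ddof=1)
        assert abs(60 - mean) <= 3.5 * sd
        pheno, _ = qc.build_contemporary_groups(toy_pheno(n=6, adg=vals, wbsf=[6.0] * 6))
        out, report = qc.filter_phenotypes(pheno)
        assert report.removed_by["adg_outlier_3.5sd"] == 0
        assert out["adg"].notna().sum() == 6

    def test_true_outlier_removed_but_other_trait_kept(self):
        # 19 peers push the lone extreme to z = 19/sqrt(20) = 4.25 > 3.5
        vals = [10.0] * 19 + [60.0]
        mean, sd = np.mean(vals), np.std(vals, ddof=1)
        assert abs(60 - mean) > 3.5 * sd
        pheno, _ = qc.build_contemporary_groups(toy_pheno(n=20, adg=vals, wbsf=[6.0] * 20))
        out, report = qc.filter_phenotypes(pheno)
        assert report.removed_by["adg_outlier_3.5sd"] == 1
        assert np.isnan(out.loc[19, "adg"])
        # removing adg never touches the wbsf record
        assert out.loc[19, "wbsf"] == 6.0
        assert out["adg"].notna().sum() == 19

    def test_size_one_cg_dropped_at_step_two(self):
        pheno = toy_pheno(n=6)
        pheno.loc[5, "herd_birth"] = "H2"  # its own CG of size 1
        pheno, _ = qc.build_contemporary_groups(pheno)
        out, report = qc.filter_phenotypes(pheno)
        assert report.removed_by["adg_outlier_3.5sd"] == 0
        assert np.isnan(out.loc[5, "adg"])

    @settings(max_examples=25, deadline=None)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_counts_conserved(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(6, 40))
        pheno = toy_pheno(
            n=n,
            adg=r.normal(0.6, 0.1, n),
            wbsf=np.where(r.random(n) < 0.2, np.nan, r.normal(6, 2, n)),
            herd_birth=r.choice(["H1", "H2"], n).tolist(),
            herd_weaning=["H1"] * n,
            herd_yearling=["H1"] * n,
        )
        pheno, _ = qc.build_contemporary_groups(pheno)
        _, report = qc.filter_phenotypes(pheno)
        report.check_conserved()
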