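"""Latent-Gaussian cohort generator: planted structure and calibration."""

import math

import numpy as np
import pytest

from comorbnet import estimate
from comorbnet.grouping import read_records
from comorbnet.synthetic import (
    CohortSpec,
    CohortSpecError,
    DiseaseSpec,
    build_latent_sigma,
    default_spec,
    generate_cohort,
    identity_lookup,
    median_split_pair,
    read_cohort,
    write_cohort,
    write_cohort_records,
)


def _spec(diseases, strata=(("M", "0-2", 100),), **kw):
    return CohortSpec(strata=strata, diseases=tuple(diseases), **kw)


class TestLatentSigma:
    def test_independence_gives_identity(self):
        spec = _spec([DiseaseSpec(f"d{i}", 0.2, i) for i in range(4)],
                     rho_within=0.0, rho_between=0.0)
        assert np.array_equal(build_latent_sigma(spec), np.eye(4))

    def test_two_blocks_give_block_diagonal(self):
        spec = _spec([DiseaseSpec("a", 0.2, 0), DiseaseSpec("b", 0.2, 0),
                      DiseaseSpec("c", 0.2, 1), DiseaseSpec("d", 0.2, 1)],
                     rho_within=0.5, rho_between=0.0)
        expected = np.array([[1, .5, 0, 0], [.5, 1, 0, 0],
                             [0, 0, 1, .5], [0, 0, .5, 1]])
        assert np.allclose(build_latent_sigma(spec), expected)

    def test_negative_within_block_correlation_rejected(self):
        # eigen oracle: the 3x3 equicorrelation matrix with rho = -0.6 has
        # eigenvalues {1.6, 1.6, 1 + 2*(-0.6) = -0.2}, so it is indefinite
        m = np.full((3, 3), -0.6) + np.diag(np.full(3, 1.6))
        assert np.linalg.eigvalsh(m).min() == pytest.approx(-0.2, abs=1e-12)
        spec = _spec([DiseaseSpec(f"d{i}", 0.2, 0) for i in range(3)],
                     rho_within=-0.6)
        with pytest.raises(CohortSpecError, match="positive definite"):
            build_latent_sigma(spec)


class TestSpecValidation:
    def test_duplicate_disease_ids_rejected(self):
        with pytest.raises(CohortSpecError, match="unique"):
            _spec([DiseaseSpec("a", 0.2, 0), DiseaseSpec("a", 0.3, 1)])

    def test_prevalence_outside_unit_interval_rejected(self):
        with pytest.raises(CohortSpecError, match="prevalence"):
            DiseaseSpec("a", 1.0, 0)

    def test_empty_strata_rejected(self):
        with pytest.raises(CohortSpecError, match="empty"):
            CohortSpec(strata=(), diseases=(DiseaseSpec("a", 0.2, 0),))

    def test_unknown_age_band_rejected(self):
        with pytest.raises(CohortSpecError, match="age band"):
            _spec([DiseaseSpec("a", 0.2, 0)], strata=(("M", "2-10", 10),))


class TestGenerateCohort:
    def test_same_seed_bit_identical(self):
        spec = default_spec(n_per_stratum=200, seed=9)
        m1, _ = generate_cohort(spec)
        m2, _ = generate_cohort(spec)
        for k in m1:
            assert np.array_equal(m1[k].indicators, m2[k].indicators)
            assert m1[k].patients == m2[k].patients

    def test_stratum_draw_depends_only_on_seed_and_label(self):
        # dropping other strata must not change a stratum's data
        full = default_spec(n_per_stratum=150, seed=4)
        only = default_spec(n_per_stratum=150, seed=4,
                            strata=(("F", "11-17", 150),))
        a = generate_cohort(full)[0][("F", "11-17")]
        b = generate_cohort(only)[0][("F", "11-17")]
        assert np.array_equal(a.indicators, b.indicators)

    def test_empirical_prevalence_within_binomial_error(self):
        spec = _spec([DiseaseSpec("a", 0.3, 0), DiseaseSpec("b", 0.3, 1)],
                     strata=(("M", "0-2", 10000),), rho_within=0.5, seed=1)
        mats, _ = generate_cohort(spec)
        se = math.sqrt(0.3 * 0.7 / 10000)
        for p in mats[("M", "0-2")].prevalences:
            assert abs(p - 0.3) < 3 * se

    def test_marginal_calibration_across_seeds(self):
        # |empirical - target| < 4 SE in at least 99% of 100 seeds at n=2000
        target = 0.2
        bound = 4 * math.sqrt(target * (1 - target) / 2000)
        ok = 0
        for s in range(100):
            spec = _spec([DiseaseSpec("a", target, 0)],
                         strata=(("F", ">65", 2000),), seed=s)
            mats, _ = generate_cohort(spec)
            ok += abs(mats[("F", ">65")].prevalences[0] - target) < bound
        assert ok >= 99

    def test_independent_diseases_show_null_tetrachoric(self):
        spec = _spec([DiseaseSpec(f"d{i}", 0.3, i) for i in range(3)],
                     strata=(("M", "3-10", 10000),), rho_within=0.0, seed=2)
        mats, _ = generate_cohort(spec)
        mat = mats[("M", "3-10")]
        se = 1.0 / math.sqrt(10000)  # crude null scale; 3 SE is generous
        for i in range(3):
            for j in range(i + 1, 3):
                res = estimate(mat.pair_table(i, j))
                assert abs(res.rho_hat) < 5 * se

    def test_latent_correlation_recovered_by_tetrachoric(self):
        # the estimator is the exact inverse of the generator's model
        errs = []
        for s in range(20):
            spec = _spec([DiseaseSpec("a", 0.3, 0), DiseaseSpec("b", 0.2, 0)],
                         strata=(("M", "18-65", 5000),), rho_within=0.5, seed=s)
            mats, _ = generate_cohort(spec)
            errs.append(estimate(mats[("M", "18-65")].pair_table(0, 1)).rho_hat - 0.5)
        assert abs(np.mean(errs)) < 0.05

    def test_stratum_sizes_reproduce_printed_shares_by_construction(self):
        # men per age band: 1605, 8954, 5318, 5985, 1660 of 23,522
        men = {"0-2": 1605, "3-10": 8954, "11-17": 5318,
               "18-65": 5985, ">65": 1660}
        spec = _spec([DiseaseSpec("a", 0.2, 0)],
                     strata=tuple(("M", band, n) for band, n in men.items()))
        mats, _ = generate_cohort(spec)
        total = sum(m.n_patients for m in mats.values())
        assert total == 23522
        assert round(100 * mats[("M", "0-2")].n_patients / total, 1) == 6.8
        assert round(100 * mats[("M", "3-10")].n_patients / total, 1) == 38.1


class TestMedianSplitPair:
    def test_null_gives_quarter_cells(self):
        t = median_split_pair(0.0, 40000, seed=0)
        for cell in (t.n11, t.n10, t.n01, t.n00):
            assert cell / t.n == pytest.approx(0.25, abs=3 * 0.5 / 200)

    def test_joint_positive_fraction_matches_orthant_closed_form(self):
        # 1/4 + arcsin(0.5)/(2*pi) = 1/4 + 1/12 = 1/3
        t = median_split_pair(0.5, 100000, seed=1)
        assert t.n11 / t.n == pytest.approx(1 / 3, abs=0.005)

    def test_near_comonotone_empties_off_diagonal(self):
        t = median_split_pair(0.999, 20000, seed=2)
        assert (t.n10 + t.n01) / t.n < 0.02

    def test_unit_correlation_rejected(self):
        with pytest.raises(ValueError):
            median_split_pair(1.0, 100)


class TestCohortIO:
    def test_indicator_file_round_trips_losslessly(self, tmp_path):
        spec = default_spec(n_per_stratum=50, seed=3,
                            strata=(("M", "0-2", 50), ("F", ">65", 40)))
        mats, truth = generate_cohort(spec)
        path = tmp_path / "cohort.tsv"
        write_cohort(mats, truth, path, tmp_path / "truth.json")
        back = read_cohort(path)
        assert set(back) == set(mats)
        for k in mats:
            assert back[k].patients == mats[k].patients
            assert back[k].diseases == mats[k].diseases
            assert np.array_equal(back[k].indicators, mats[k].indicators)

    def test_records_file_feeds_the_grouping_reader(self, tmp_path):
        spec = default_spec(n_per_stratum=60, seed=5,
                            strata=(("F", "3-10", 60),))
        mats, _ = generate_cohort(spec)
        path = tmp_path / "records.tsv"
        write_cohort_records(mats, path)
        records, rejects = read_records(path)
        assert len(rejects) == 0
        assert len(records) == int(mats[("F", "3-10")].indicators.sum())

    def test_identity_lookup_is_a_valid_code_lookup(self):
        lk = identity_lookup(["a", "b", "c"])
        assert lk.categories == {0: "a", 1: "b", 2: "c"}
        assert all(lk.chronic.values())
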