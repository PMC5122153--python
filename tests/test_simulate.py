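"""Synthetic cohort generator: pedigrees, records, CNVs, fixtures."""

import io
import math

import numpy as np
import pandas as pd
import pytest
from cnvliab.relatedness import a_matrix
from cnvliab.simulate import (
    SimConfig,
    make_cohort,
    prepare_period_outcomes,
    record_animals,
    sim_array_signals,
    sim_breeding_values,
    sim_cnv_genotypes,
    sim_junction_fixture,
    sim_pedigree,
    sim_records,
)
from cnvliab.structvar import find_homology_arms
from cnvliab.threshold_model import VarianceComponents


def small_config(**kw):
    defaults = dict(
        n_founders=30, founder_sires=5, n_generations=1,
        n_offspring_per_generation=60, records_per_cow=2, rng_seed=1,
    )
    defaults.update(kw)
    return SimConfig(**defaults)


class TestPedigree:
    def test_founders_only_yields_identity_a_matrix(self):
        cfg = small_config(n_founders=10, founder_sires=2, n_generations=0)
        ped = sim_pedigree(cfg)
        assert len(ped) == 10
        assert ped["sire"].isna().all() and ped["dam"].isna().all()
        np.testing.assert_allclose(a_matrix(ped[["animal", "sire", "dam"]]).values,
                                   np.eye(10))

    def test_offspring_parent_relationship_is_half(self):
        cfg = small_config(n_founders=2, founder_sires=1,
                           n_offspring_per_generation=3)
        ped = sim_pedigree(cfg)
        A = a_matrix(ped[["animal", "sire", "dam"]])
        child = ped[ped["generation"] == 1].iloc[-1]
        assert A.values[A.index_of(child["animal"]), A.index_of(child["sire"])] == 0.5

    def test_seeded_pedigree_is_byte_identical(self):
        cfg = small_config(n_founders=50, founder_sires=10, n_generations=3,
                           n_offspring_per_generation=40, rng_seed=99)
        buf1, buf2 = io.StringIO(), io.StringIO()
        sim_pedigree(cfg).to_csv(buf1, index=False)
        sim_pedigree(cfg).to_csv(buf2, index=False)
        assert buf1.getvalue() == buf2.getvalue()

    def test_negative_generations_rejected(self):
        with pytest.raises(ValueError):
            small_config(n_generations=-1)


class TestCnvGenotypes:
    def test_zero_frequency_means_all_two_copies(self, rng):
        copies, n_redrawn = sim_cnv_genotypes(0.0, 500, rng=rng)
        assert (copies == 2).all() and n_redrawn == 0

    def test_carrier_fraction_matches_hardy_weinberg(self, rng):
        n = 100_000
        copies, _ = sim_cnv_genotypes(0.024, n, forbid_homozygotes=False, rng=rng)
        expected = 2 * 0.024 * 0.976
        se = math.sqrt(expected * (1 - expected) / n)
        assert abs((copies == 1).mean() - expected) < 3 * se

    def test_forbidding_homozygotes_removes_zero_copy_animals(self, rng):
        with pytest.warns(UserWarning, match="redrawn"):
            copies, n_redrawn = sim_cnv_genotypes(0.5, 2_000, True, rng)
        assert (copies >= 1).all()
        assert n_redrawn > 0

    def test_major_allele_frequency_rejected(self, rng):
        with pytest.raises(ValueError, match="minor"):
            sim_cnv_genotypes(0.6, 10, rng=rng)


class TestRecords:
    def test_incidence_matches_targets_without_random_effects(self):
        """With zero genetic/permanent variance and no fixed-effect spread,
        each window's realized incidence among at-risk records matches its
        calibration target within 3 binomial SD."""
        cfg = SimConfig(
            n_founders=100_002, founder_sires=2, n_generations=0, records_per_cow=1,
            variance_components=VarianceComponents(0.0, 0.0, 1.0),
            fixed_effect_sd=0.0, age_slope=0.0, rng_seed=12,
        )
        ped = sim_pedigree(cfg)
        recs, _ = sim_records(ped, cfg)
        outs = prepare_period_outcomes(recs, cfg.period_definitions)
        for (lo, hi), target in zip(cfg.period_definitions, cfg.target_incidence):
            d = outs[f"{lo}-{hi}"]
            se = math.sqrt(target * (1 - target) / len(d))
            assert abs(d["y"].mean() - target) < 3 * se, (lo, hi)

    def test_null_cnv_effect_leaves_carriers_unshifted(self):
        cfg = SimConfig(
            n_founders=20_002, founder_sires=2, n_generations=0, records_per_cow=1,
            variance_components=VarianceComponents(0.0, 0.0, 1.0),
            cnv_liability_effect=0.0, rng_seed=3,
        )
        ped = sim_pedigree(cfg)
        cows = record_animals(ped)
        carriers = cows[: len(cows) // 2]
        recs, _ = sim_records(ped, cfg, carriers=carriers)
        d = prepare_period_outcomes(recs, cfg.period_definitions)["30-60"]
        is_c = d["animal"].isin(carriers)
        diff = d.loc[is_c, "y"].mean() - d.loc[~is_c, "y"].mean()
        se = math.sqrt(2 * 0.22 * 0.78 / (len(d) / 2))
        assert abs(diff) < 3 * se

    def test_positive_cnv_effect_raises_carrier_incidence(self):
        cfg = SimConfig(
            n_founders=20_002, founder_sires=2, n_generations=0, records_per_cow=1,
            variance_components=VarianceComponents(0.0, 0.0, 1.0),
            cnv_liability_effect=0.5, rng_seed=3,
        )
        ped = sim_pedigree(cfg)
        cows = record_animals(ped)
        carriers = cows[: len(cows) // 2]
        recs, _ = sim_records(ped, cfg, carriers=carriers)
        d = prepare_period_outcomes(recs, cfg.period_definitions)["30-60"]
        is_c = d["animal"].isin(carriers)
        assert d.loc[is_c, "y"].mean() > d.loc[~is_c, "y"].mean() + 0.05

    def test_breeding_value_variance_recovered_in_one_draw(self):
        """Quadratic form a'A^-1 a / n concentrates at sigma2_a."""
        cfg = small_config(n_founders=350, founder_sires=50,
                           n_offspring_per_generation=2_000, rng_seed=5)
        ped = sim_pedigree(cfg)
        a = sim_breeding_values(ped[["animal", "sire", "dam"]], 0.3,
                                np.random.default_rng(8))
        A = a_matrix(ped[["animal", "sire", "dam"]])
        n = len(a)
        q = a.to_numpy() @ np.linalg.solve(A.values, a.to_numpy()) / n
        assert q == pytest.approx(0.3, rel=4 * math.sqrt(2.0 / n))

    def test_breeding_value_covariance_matches_a_sigma2(self):
        """Sample covariance over replicate draws approaches A * sigma2_a in
        Frobenius norm (expected relative error ~ sqrt(n/reps))."""
        cfg = small_config(n_founders=50, founder_sires=10,
                           n_offspring_per_generation=100, rng_seed=6)
        ped = sim_pedigree(cfg)[["animal", "sire", "dam"]]
        A = a_matrix(ped)
        n = len(A.ids)
        reps = 30_000
        g = np.random.default_rng(13)
        L = np.linalg.cholesky(A.values + 1e-10 * np.eye(n))
        draws = (L @ g.standard_normal((n, reps))) * math.sqrt(0.3)
        C = np.cov(draws)
        target = 0.3 * A.values
        rel = np.linalg.norm(C - target) / np.linalg.norm(target)
        assert rel < 0.10


class TestPeriodOutcomes:
    def test_return_day_routing_and_risk_set_exclusion(self):
        recs = pd.DataFrame(
            {
                "animal": ["a", "b", "c"],
                "parity": [1, 1, 1],
                "farm": ["F0"] * 3,
                "ym": ["Y0"] * 3,
                "age": [24.0] * 3,
                "return_day": [25.0, np.nan, 70.0],
            }
        )
        outs = prepare_period_outcomes(recs)
        assert outs["18-29"].set_index("animal")["y"].to_dict() == {"a": 1, "b": 0, "c": 0}
        # the day-25 returner leaves the 30-60 risk set entirely
        assert "a" not in set(outs["30-60"]["animal"])
        assert outs["30-60"].set_index("animal")["y"].to_dict() == {"b": 0, "c": 0}
        assert outs["61-90"].set_index("animal")["y"].to_dict() == {"b": 0, "c": 1}
        # no return at all: present and 0 in every window
        for key, df in outs.items():
            assert df.set_index("animal")["y"].get("b") == 0

    def test_negative_day_rejected(self):
        recs = pd.DataFrame(
            {"animal": ["a"], "parity": [1], "farm": ["F0"], "ym": ["Y0"],
             "age": [24.0], "return_day": [-1.0]}
        )
        with pytest.raises(ValueError, match="negative"):
            prepare_period_outcomes(recs)


class TestArraySignals:
    def test_lrr_shift_confined_to_deletion_in_carriers(self, rng):
        markers = np.arange(100, 2100, 100)
        df = sim_array_signals((500, 1500), ["carrier"], ["carrier", "ctrl"],
                               markers, rng)
        inside = (df["pos"] >= 500) & (df["pos"] <= 1500)
        car = df["animal"] == "carrier"
        assert df.loc[car & inside, "lrr"].mean() == pytest.approx(-0.45, abs=0.2)
        assert df.loc[car & ~inside, "lrr"].mean() == pytest.approx(0.0, abs=0.2)
        assert df.loc[~car, "lrr"].mean() == pytest.approx(0.0, abs=0.1)

    def test_carrier_baf_has_no_heterozygous_band_inside_deletion(self, rng):
        markers = np.arange(100, 2100, 20)
        df = sim_array_signals((500, 1500), ["x"], ["x"], markers, rng)
        inside = (df["pos"] >= 500) & (df["pos"] <= 1500)
        baf = df.loc[inside, "baf"]
        assert not ((baf > 0.3) & (baf < 0.7)).any()

    def test_no_markers_in_deletion_warns(self, rng):
        with pytest.warns(UserWarning, match="no markers"):
            sim_array_signals((500, 600), [], ["a"], np.array([10, 2000]), rng)


class TestJunctionFixture:
    def test_round_trip_recovers_arm_length(self):
        fx = sim_junction_fixture(63, 1_000, 120, rng=4)
        jm = find_homology_arms(fx.reference, fx.junction_read)
        assert jm.arm_length == 63
        assert jm.ambiguity == 63
        assert jm.deletion_length == fx.truth["deletion_length"] == 1_000
        assert list(jm.left_arm) == fx.truth["left_arm"]
        assert list(jm.right_arm) == fx.truth["right_arm"]

    def test_zero_arm_gives_unique_breakpoint(self):
        fx = sim_junction_fixture(0, 500, 100, rng=5)
        jm = find_homology_arms(fx.reference, fx.junction_read)
        assert jm.arm_length == 0
        assert jm.ambiguity == 0
        assert jm.deletion_length == 500

    def test_same_seed_gives_identical_fasta_bytes(self, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        sim_junction_fixture(20, 300, 60, rng=11).write(d1)
        sim_junction_fixture(20, 300, 60, rng=11).write(d2)
        assert (d1 / "reference.fasta").read_bytes() == (d2 / "reference.fasta").read_bytes()
        assert (d1 / "junction.fasta").read_bytes() == (d2 / "junction.fasta").read_bytes()

    def test_parameter_validation(self):
        with pytest.raises(ValueError, match="exceed"):
            sim_junction_fixture(63, 50, 100)
        with pytest.raises(ValueError, match="anchor"):
            sim_junction_fixture(10, 100, 5)


class TestCohort:
    def test_cohort_invariants_hold(self):
        cfg = small_config(rng_seed=21)
        cohort = make_cohort(cfg)
        assert set(cohort.records["animal"]) <= set(cohort.pedigree["animal"])
        assert (cohort.cnv_copy_number >= 1).all()
        assert cohort.snp_genotypes.shape[0] == len(cohort.cnv_copy_number)
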