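"""Two-locus pedigree likelihoods, lod scores, marginalization and the
maximum-likelihood penetrance search."""

import math

import numpy as np
import pytest

from craniostats import (
    TwoLocusPenetranceModel,
    family_likelihood,
    family_lod,
    lod_to_odds,
    marginalize_missing_parent,
    ml_search,
    null_likelihood,
    penetrance_of,
    single_locus_comparison,
    total_lod,
)
from craniostats.errors import (
    MendelianError,
    NoConsistentCompletionError,
    ValidationError,
)
from craniostats.linkage import LinkageResult, default_penetrance_grid
from craniostats.pedigree import PedigreeGraph
from craniostats.simulate import SimulationConfig, simulate_pedigrees

from conftest import brute_force_likelihood, make_ind


class TestPenetranceModel:
    @pytest.mark.parametrize(
        "carrier,dose,expected",
        [
            (True, 1, 1.0),
            (True, 2, 1.0),
            (True, 0, 0.09),
            (False, 1, 0.0008),
            (False, 2, 0.0032),
            (False, 0, 0.0002),
        ],
    )
    def test_class_mapping(self, ml_model, carrier, dose, expected):
        assert penetrance_of(carrier, dose, ml_model) == pytest.approx(expected)

    def test_parameter_validation(self):
        with pytest.raises(ValidationError):
            TwoLocusPenetranceModel(f_S=1.2)
        with pytest.raises(ValidationError):
            TwoLocusPenetranceModel(q_B=0.0)
        with pytest.raises(ValidationError):
            TwoLocusPenetranceModel(theta=0.1)


class TestFamilyLikelihood:
    def test_fully_observed_product(self, ml_model, oracle_trio):
        # 0.91 (unaffected carrier, no risk allele) * 0.9992 (unaffected,
        # one risk allele) * 1.0 (affected carrier with risk allele)
        assert family_likelihood(oracle_trio, ml_model) == pytest.approx(
            0.91 * 0.9992 * 1.0, rel=1e-12
        )

    def test_degenerate_model_equals_null(self, oracle_trio):
        m = TwoLocusPenetranceModel(
            f_both=5e-4, f_S=5e-4, f_B1=5e-4, f_B2=5e-4, f_0=5e-4
        )
        assert family_likelihood(oracle_trio, m) == pytest.approx(
            null_likelihood(oracle_trio, 5e-4), rel=1e-12
        )

    def test_unaffected_obligate_carrier_zeroes_likelihood(self, ml_model):
        ped = PedigreeGraph(
            "Z", [make_ind("A", affected=False, carrier=True, dose=2)]
        )
        assert family_likelihood(ped, ml_model) == 0.0
        assert family_lod(ped, ml_model) == float("-inf")

    def test_mendelian_inconsistency_raises(self, ml_model):
        ped = PedigreeGraph(
            "B",
            [
                make_ind("F", carrier=False, dose=0),
                make_ind("M", carrier=False, dose=0),
                make_ind("C", "F", "M", affected=True, carrier=False, dose=1),
            ],
        )
        with pytest.raises(MendelianError):
            family_likelihood(ped, ml_model)
        with pytest.raises(NoConsistentCompletionError):
            family_likelihood(ped, ml_model, validate=False)


class TestNullLikelihood:
    def test_trio_value(self, oracle_trio):
        assert null_likelihood(oracle_trio, 0.0005) == pytest.approx(
            0.0005 * 0.9995**2, rel=1e-12
        )

    def test_all_affected_power(self, ml_model):
        ped = PedigreeGraph(
            "A", [make_ind(f"I{k}", affected=True, carrier=True, dose=1) for k in range(4)]
        )
        assert null_likelihood(ped, 0.01) == pytest.approx(0.01**4)

    def test_vanishing_prevalence_limit(self):
        ped = PedigreeGraph("U", [make_ind("I", affected=False, carrier=False, dose=0)])
        assert null_likelihood(ped, 1e-12) == pytest.approx(1.0)


class TestLod:
    def test_oracle_trio_lod(self, ml_model, oracle_trio):
        expected = math.log10(0.909272) - math.log10(0.0005 * 0.9995**2)
        assert family_lod(oracle_trio, ml_model, 0.0005) == pytest.approx(expected)

    def test_degenerate_model_gives_zero(self, oracle_trio):
        m = TwoLocusPenetranceModel(
            f_both=5e-4, f_S=5e-4, f_B1=5e-4, f_B2=5e-4, f_0=5e-4
        )
        assert family_lod(oracle_trio, m, 5e-4) == pytest.approx(0.0, abs=1e-12)

    def test_additivity(self, ml_model, oracle_trio):
        twin = PedigreeGraph("T2", [make_ind(m.iid, m.father_id, m.mother_id, m.sex,
                                             m.affected, m.is_proband,
                                             m.smad6_carrier, m.bmp2_dose)
                                    for m in oracle_trio.members])
        single = family_lod(oracle_trio, ml_model)
        result = total_lod([oracle_trio, twin], ml_model)
        assert result.total_lod == pytest.approx(2 * single, rel=1e-12)
        assert result.per_family_lod["T1"] == pytest.approx(single)

    def test_duplicate_family_ids_rejected(self, ml_model, oracle_trio):
        with pytest.raises(ValidationError, match="duplicate"):
            total_lod([oracle_trio, oracle_trio], ml_model)

    def test_result_consistency_enforced(self, ml_model):
        with pytest.raises(ValidationError):
            LinkageResult({"a": 1.0, "b": 2.0}, 4.0, ml_model, "null")

    def test_lod_odds_conversion(self):
        assert lod_to_odds(7.37) == pytest.approx(2.3e7, rel=0.02)
        assert math.log10(lod_to_odds(3.2)) == pytest.approx(3.2)


def _quartet_missing_father(ml_model):
    return PedigreeGraph(
        "Q",
        [
            make_ind("F"),  # entirely ungenotyped, phenotype unknown
            make_ind("M", affected=False, carrier=False, dose=1),
            make_ind("C1", "F", "M", affected=True, proband=True, carrier=True, dose=2),
            make_ind("C2", "F", "M", affected=False, carrier=False, dose=0),
        ],
    )


class TestMarginalization:
    def test_forced_risk_transmission(self, ml_model):
        """Child dose 2 with a dose-1 parent forces the missing parent to
        transmit a risk allele; the marginalized likelihood matches the
        joint-enumeration oracle exactly."""
        ped = PedigreeGraph(
            "P",
            [
                make_ind("F", affected=False, carrier=False, dose=1),
                make_ind("M", affected=False),
                make_ind("C", "F", "M", affected=True, proband=True, carrier=True,
                         dose=2, de_novo=True),
            ],
        )
        ours = marginalize_missing_parent(ped, ml_model)
        assert ours == pytest.approx(brute_force_likelihood(ped, ml_model), rel=1e-12)
        assert ours > 0

    @pytest.mark.parametrize("builder", [_quartet_missing_father])
    def test_oracle_equivalence(self, ml_model, builder):
        ped = builder(ml_model)
        assert family_likelihood(ped, ml_model) == pytest.approx(
            brute_force_likelihood(ped, ml_model), rel=1e-12
        )

    def test_three_generation_two_missing(self, ml_model):
        ped = PedigreeGraph(
            "G3",
            [
                make_ind("GF"),  # missing founder
                make_ind("GM", affected=False, carrier=True, dose=0),
                make_ind("F", "GF", "GM", affected=False, carrier=True, dose=0),
                make_ind("M"),  # missing founder
                make_ind("C1", "F", "M", affected=True, proband=True, carrier=True, dose=1),
                make_ind("C2", "F", "M", affected=False, carrier=False, dose=0),
            ],
        )
        assert family_likelihood(ped, ml_model) == pytest.approx(
            brute_force_likelihood(ped, ml_model), rel=1e-11
        )

    def test_unconnected_missing_parent_is_neutral(self, ml_model):
        """A fully missing founder with unknown phenotype and no genotyped
        constraints leaves the likelihood of the rest unchanged."""
        base = PedigreeGraph(
            "B",
            [
                make_ind("M", affected=False, carrier=True, dose=0),
                make_ind("F", affected=None, carrier=False, dose=0),
                make_ind("C", "F", "M", affected=False, carrier=False, dose=0),
            ],
        )
        with_ghost = PedigreeGraph(
            "B2",
            [
                make_ind("M", affected=False, carrier=True, dose=0),
                make_ind("F"),
                make_ind("C", "F", "M", affected=False, carrier=False, dose=0),
            ],
        )
        lik_base = family_likelihood(base, ml_model)
        lik_ghost = family_likelihood(with_ghost, ml_model)
        # the ghost father's only constraint is transmitting a non-risk
        # allele; phenotype unknown, so no penetrance factor enters
        assert lik_ghost == pytest.approx(
            brute_force_likelihood(with_ghost, ml_model), rel=1e-12
        )
        assert lik_ghost == pytest.approx(lik_base, rel=1e-9)

    def test_high_frequency_limit_matches_observed(self):
        """With the SNP risk allele near fixation every completion is dose 2,
        so marginalization reproduces the fully observed likelihood."""
        m = TwoLocusPenetranceModel(q_B=1 - 1e-9)
        missing = PedigreeGraph(
            "H",
            [
                make_ind("F", affected=False, carrier=True, dose=2),
                make_ind("M", affected=False, carrier=False),  # dose missing
                make_ind("C", "F", "M", affected=True, proband=True, carrier=True, dose=2),
            ],
        )
        observed = PedigreeGraph(
            "H2",
            [
                make_ind("F", affected=False, carrier=True, dose=2),
                make_ind("M", affected=False, carrier=False, dose=2),
                make_ind("C", "F", "M", affected=True, proband=True, carrier=True, dose=2),
            ],
        )
        assert family_likelihood(missing, m) == pytest.approx(
            family_likelihood(observed, m), rel=1e-6
        )

    def test_too_many_missing_members(self, ml_model):
        ped = PedigreeGraph("L", [make_ind(f"I{k}") for k in range(8)])
        with pytest.raises(ValidationError, match="marginalization bound"):
            family_likelihood(ped, ml_model)


class TestAscertainmentConditioning:
    def test_proband_conditioning_divides_by_penetrance(self, ml_model, oracle_trio):
        plain = family_likelihood(oracle_trio, ml_model)
        conditioned = family_likelihood(oracle_trio, ml_model, condition_on_proband=True)
        # proband is an affected carrier with the risk allele: f = 1.0
        assert conditioned == pytest.approx(plain / 1.0)
        lod_plain = family_lod(oracle_trio, ml_model, 0.0005)
        lod_cond = family_lod(oracle_trio, ml_model, 0.0005, condition_on_proband=True)
        assert lod_cond == pytest.approx(lod_plain + math.log10(0.0005), rel=1e-9)


class TestMLSearch:
    def test_grid_with_only_truth_returns_it(self, ml_model, oracle_trio):
        grid = {name: [getattr(ml_model, name)] for name in
                ("f_both", "f_S", "f_B1", "f_B2", "f_0")}
        res = ml_search([oracle_trio], grid_spec=grid)
        assert res.model.f_vector.tolist() == ml_model.f_vector.tolist()

    def test_empty_grid_rejected(self, oracle_trio):
        with pytest.raises(ValidationError, match="empty grid"):
            ml_search([oracle_trio], grid_spec={"f_S": []})

    def test_recovers_generating_model(self):
        """13 ascertained kindreds simulated under the maximum-likelihood
        model: the searched f_both is exactly 1 and f_S lands within one
        log2 grid step of 0.09."""
        peds = simulate_pedigrees(SimulationConfig(seed=11))
        res = ml_search(peds)
        assert res.model.f_both == 1.0
        grid = default_penetrance_grid()
        nearest = min(grid, key=lambda v: abs(math.log(v) - math.log(0.09)))
        i = grid.index(nearest)
        assert res.model.f_S in grid[max(i - 1, 0): i + 2]

    def test_null_data_collapse(self):
        """Families whose phenotypes ignore genotype support no linkage: the
        searched lod stays near zero and far below the digenic cohorts'."""
        null_model = TwoLocusPenetranceModel(
            f_both=0.01, f_S=0.01, f_B1=0.01, f_B2=0.01, f_0=0.01
        )
        cfg = SimulationConfig(
            seed=5,
            penetrance=null_model,
            ascertain=False,
            n_kindreds=20,
            condition_parents_unaffected=False,
        )
        peds = simulate_pedigrees(cfg)
        res = ml_search(peds, prevalence=0.01)
        linked = ml_search(simulate_pedigrees(SimulationConfig(seed=5)))
        assert res.total_lod < 2.0  # small overfitting headroom only
        assert linked.total_lod > 10.0


class TestSingleLocusComparison:
    def test_identity_when_models_coincide(self):
        m = TwoLocusPenetranceModel(f_both=0.2, f_S=0.2, f_B1=5e-4, f_B2=5e-4, f_0=5e-4)
        peds = simulate_pedigrees(SimulationConfig(seed=21, penetrance=m))
        res = single_locus_comparison(
            peds, m, m1_grid={"f_carrier": [0.2], "f_noncarrier": [5e-4]}
        )
        assert res["likelihood_ratio"] == pytest.approx(1.0, rel=1e-9)

    def test_digenic_data_favor_two_locus_model(self):
        peds = simulate_pedigrees(SimulationConfig(seed=31))
        res = single_locus_comparison(peds, TwoLocusPenetranceModel())
        assert res["likelihood_ratio"] > 1.0

    def test_ratio_grows_with_kindred_count(self):
        small = simulate_pedigrees(SimulationConfig(seed=41, n_kindreds=6))
        large = simulate_pedigrees(SimulationConfig(seed=41, n_kindreds=24))
        m = TwoLocusPenetranceModel()
        r_small = single_locus_comparison(small, m)["likelihood_ratio"]
        r_large = single_locus_comparison(large, m)["likelihood_ratio"]
        assert r_large > r_small > 1.0

    def test_single_locus_data_yield_ratio_near_one(self):
        m1 = TwoLocusPenetranceModel(f_both=0.2, f_S=0.2, f_B1=5e-4, f_B2=5e-4, f_0=5e-4)
        peds = simulate_pedigrees(SimulationConfig(seed=51, penetrance=m1))
        best2 = ml_search(peds)
        res = single_locus_comparison(peds, best2.model)
        # the two-locus advantage on truly single-locus data is overfitting
        # headroom only: a couple of orders of magnitude, not the explosive
        # support real digenic data produce
        assert math.log10(res["likelihood_ratio"]) < 2.0
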