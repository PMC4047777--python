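import numpy as np
import pytest

from equicea import (
    StratumKey,
    canonical_scenarios,
    resolve_effective_params,
    validate_bundle,
)
from equicea.params import (
    BundleLookupError,
    DeprivationWeights,
    DisabilityWeightSet,
    PhaseSchedule,
)
from equicea.strata import DEPRIVATION_TERTILES, stratum_grid

# the five-model switch matrix: excess-mortality source, DWs, background
# mortality source, pYLD envelope (incidence is always ethnic-specific)
SWITCH_MATRIX = {
    1: ("reference_group", False, "reference_group", False),
    2: ("ethnic_specific", False, "reference_group", False),
    3: ("ethnic_specific", True, "reference_group", False),
    4: ("ethnic_specific", True, "ethnic_specific", False),
    5: ("ethnic_specific", True, "ethnic_specific", True),
}


def test_canonical_scenarios_match_switch_matrix():
    scenarios = canonical_scenarios()
    assert [s.model_id for s in scenarios] == [1, 2, 3, 4, 5]
    for s in scenarios:
        excess, dw, background, pyld = SWITCH_MATRIX[s.model_id]
        assert s.excess_mortality_source == excess
        assert s.disability_weights_on == dw
        assert s.background_mortality_source == background
        assert s.pyld_on == pyld


def test_model3_differs_from_model2_only_by_disability_weights():
    m2, m3 = canonical_scenarios()[1:3]
    d2, d3 = m2.model_dump(), m3.model_dump()
    diff = {k for k in d2 if d2[k] != d3[k]}
    assert diff == {"model_id", "disability_weights_on"}


class TestResolveEffectiveParams:
    MAORI = StratumKey("maori", "female", "65-69", "dep7_10")

    def test_model1_maori_excess_equals_matching_non_maori(self, bundle):
        m1 = canonical_scenarios()[0]
        eff = resolve_effective_params(m1, bundle, "lung", self.MAORI)
        ref = bundle.excess_mortality["lung"].get(
            self.MAORI._replace(ethnicity="non_maori")
        )
        assert eff.excess_annual_rate == ref
        assert eff.background_ethnicity == "non_maori"
        assert eff.dw == DisabilityWeightSet.zero()
        assert not eff.pyld_by_band.any()

    def test_model2_maori_background_uses_reference_decline(self, bundle):
        m2 = canonical_scenarios()[1]
        eff = resolve_effective_params(m2, bundle, "lung", self.MAORI)
        assert eff.background_ethnicity == "non_maori"
        assert bundle.life_table.annual_decline[eff.background_ethnicity] == 0.0175

    def test_model5_is_identity_passthrough(self, bundle):
        m5 = canonical_scenarios()[4]
        eff = resolve_effective_params(m5, bundle, "breast", self.MAORI)
        assert eff.excess_annual_rate == bundle.excess_mortality["breast"].get(self.MAORI)
        assert eff.background_ethnicity == "maori"
        assert eff.dw == bundle.disability_weights["breast"]
        np.testing.assert_array_equal(
            eff.pyld_by_band, bundle.pyld.by_band("maori", "female")
        )

    @pytest.mark.parametrize("model_idx", range(5))
    def test_reference_group_strata_unchanged_under_every_scenario(
        self, bundle, model_idx
    ):
        scenario = canonical_scenarios()[model_idx]
        key = StratumKey("non_maori", "male", "50-54", "dep1_3")
        eff = resolve_effective_params(scenario, bundle, "colon", key)
        assert eff.excess_annual_rate == bundle.excess_mortality["colon"].get(key)
        assert eff.background_ethnicity == "non_maori"
        assert eff.incidence_rate == bundle.incidence["colon"].get(key)

    def test_resolution_is_deterministic(self, bundle):
        m1 = canonical_scenarios()[0]
        a = resolve_effective_params(m1, bundle, "lung", self.MAORI)
        b = resolve_effective_params(m1, bundle, "lung", self.MAORI)
        assert a.excess_annual_rate == b.excess_annual_rate
        np.testing.assert_array_equal(a.pyld_by_band, b.pyld_by_band)

    def test_missing_stratum_names_table_and_key(self, bundle):
        m5 = canonical_scenarios()[4]
        broken = bundle.excess_mortality["lung"]
        removed = broken.values.pop(self.MAORI)
        try:
            with pytest.raises(BundleLookupError, match="excess_mortality"):
                resolve_effective_params(m5, bundle, "lung", self.MAORI)
        finally:
            broken.values[self.MAORI] = removed

    def test_configurable_reference_ethnicity(self, bundle):
        m1 = canonical_scenarios()[0]
        key = StratumKey("non_maori", "female", "65-69", "dep4_6")
        eff = resolve_effective_params(
            m1, bundle, "lung", key, reference_ethnicity="maori"
        )
        assert eff.excess_annual_rate == bundle.excess_mortality["lung"].get(
            key._replace(ethnicity="maori")
        )


class TestValidateBundle:
    def test_complete_synthetic_bundle_is_clean(self, bundle):
        report = validate_bundle(bundle)
        assert report.ok, report.violations

    def test_out_of_range_disability_weight_names_phase(self, bundle):
        bad = DisabilityWeightSet.model_construct(
            diagnosis=1.2, preterminal=0.5, terminal=0.5, remission=0.3
        )
        original = bundle.disability_weights["lung"]
        bundle.disability_weights["lung"] = bad
        try:
            report = validate_bundle(bundle)
        finally:
            bundle.disability_weights["lung"] = original
        assert any("diagnosis" in v for v in report.violations)

    def test_unnormalised_deprivation_weights_flagged(self, bundle):
        original = bundle.deprivation_weights
        bundle.deprivation_weights = DeprivationWeights.model_construct(
            maori=(0.3, 0.3, 0.3), non_maori=original.non_maori
        )
        try:
            report = validate_bundle(bundle)
        finally:
            bundle.deprivation_weights = original
        assert any("sums to" in v for v in report.violations)

    def test_missing_stratum_reported(self, bundle):
        key = stratum_grid("colon")[0]
        removed = bundle.incidence["colon"].values.pop(key)
        try:
            report = validate_bundle(bundle)
        finally:
            bundle.incidence["colon"].values[key] = removed
        assert any("missing stratum" in v for v in report.violations)


def test_phase_schedule_requires_cure_after_phases():
    with pytest.raises(ValueError, match="cure_months"):
        PhaseSchedule(
            diagnosis_months=5, preterminal_months=5, terminal_months=1, cure_months=11
        )


def test_deprivation_grid_enumerates_three_tertiles():
    assert len(DEPRIVATION_TERTILES) == 3
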