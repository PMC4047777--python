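"""equicea — ethnicity-stratified Markov cost-utility modelling.

A three-state Markov cohort model (alive with cancer, death from the
cancer, death from other causes) on a monthly cycle, valued in
health-adjusted life years (HALYs) and NZ$ costs, with a five-step
layering of ethnic heterogeneity in the input parameters and standard
cost-effectiveness reporting (incremental HALYs, per-100,000 gains,
relative risks, ICERs).
"""

from importlib.resources import files as _files

__version__ = "0.1.0"

from .engine import (
    AbsorptionDistribution,
    apply_intervention,
    run_cohort,
    simulate_cohort_mc,
)
from .io import read_bundle, write_bundle
from .lifetable import competing_split, project_background_rate, rate_to_prob
from .params import (
    BundleLookupError,
    CostTable,
    DeprivationWeights,
    DisabilityWeightSet,
    InterventionSpec,
    LifeTable,
    ParameterBundle,
    PhaseSchedule,
    PopulationTable,
    PyldTable,
    RateTable,
    ScenarioSpec,
    canonical_scenarios,
    reference_disability_weights,
    reference_phase_schedules,
    resolve_effective_params,
    validate_bundle,
)
from .pipeline import (
    aggregate_deprivation,
    compute_icer,
    expected_value,
    pct_change,
    per_100k,
    rr,
    run_model_grid,
    sensitivity_grid,
    reporting_view,
    value_all_outcomes,
)
from .strata import AGE_BANDS, CANCERS, StratumKey
from .synthetic import SyntheticConfig, generate_bundle, generate_population
from .trajectory import (
    Trajectory,
    build_trajectory,
    discount_factor,
    haly_weight,
    value_costs,
    value_halys,
)


def fixture_bundle_path() -> str:
    """Path to the small synthetic bundle shipped with the package."""
    return str(_files("equicea").joinpath("data/bundle"))
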