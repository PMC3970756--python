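"""afferentsim: tipping-point analysis of primary-afferent excitability.

Simulates a hybrid Morris-Lecar membrane model with added subthreshold
conductances, maps the bifurcation structure that separates normal
(onset-only spiking) from neuropathic (repetitive spiking / MPOs /
bursting) excitability, titrates distance to the tipping point with
virtual dynamic-clamp conductances, generates synthetic afferent
cohorts, and applies exact statistics to conversion counts.
"""

from .model_core import (
    AHPParams,
    CellModel,
    LinoidGateParams,
    MLCoreParams,
    NoiseSpec,
    State,
    SubthresholdChannel,
    gate_kinetics,
    membrane_currents,
    potassium_channel,
    rhs,
    sodium_channel,
)
from .simulate import (
    StimulusProtocol,
    Trace,
    find_holding_current,
    integrate,
    stationary_current,
)
from .dynamics import (
    BifurcationDiagram1D,
    Equilibrium,
    TippingMap,
    find_equilibria,
    find_hopf,
    scan_Istim,
    tipping_map,
)
from .classify import (
    ExcitabilityLabel,
    TitrationResult,
    classify_excitability,
    detect_bursts,
    detect_mpo,
    detect_spikes,
    titrate_to_tipping,
)
from .experiments import (
    PredictionOutcome,
    density_conversion,
    measure_passive,
    measure_subthreshold_K_density,
    run_all_predictions,
    run_prediction,
    spike_threshold_voltage,
)
from .population import (
    CohortSpec,
    InjurySpec,
    apply_injury,
    cohort_experiment,
    conversion_table,
    naive_cutaneous_spec,
    naive_muscle_spec,
    sample_cohort,
)
from .stats import (
    ContingencyTable2x2,
    TestResult,
    conversion_tables,
    fisher_exact,
    mann_whitney_u,
)
from .config import RunConfig, config_hash, load_config, save_config

__version__ = "0.1.0"

#: added-conductance settings used as reference operating points:
#: "normal" sits just outside the Hopf-bearing regime, "neuropathic"
#: just inside it (mS/cm^2)
NORMAL_GNA_GK = (2.0, 2.5)
NEUROPATHIC_GNA_GK = (2.5, 2.0)


def reference_model(kind: str = "normal") -> CellModel:
    """Reference cell: base core plus Na/K channels at a named setting."""
    if kind == "base":
        return CellModel()
    try:
        gNa, gK = {"normal": NORMAL_GNA_GK, "neuropathic": NEUROPATHIC_GNA_GK}[kind]
    except KeyError:
        raise ValueError(f"unknown reference kind {kind!r}") from None
    return CellModel(channels=(sodium_channel(gNa), potassium_channel(gK)))
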