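"""Bridge from receptor pharmacology to circuit coupling signals.

For every implemented receptor this module computes the activation *signal*
``(occ_ligand + alpha * occ_drug) * expression_scale`` at the genotype- and
pathology-adjusted basal neurotransmitter tone, for either the cortical or the
striatal compartment.  The circuit models consume these signals (and the
signals of a fixed reference condition) as gain modulators.

The schizophrenia disease state enters here as well: a hyperdopaminergic
striatum, a hypodopaminergic cortex, fractional glutamatergic and GABAergic
deficits and raised background noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping

from .genotypes import GenotypeEffects, REFERENCE_GENOTYPE, genotype_effects
from .pharmacology import (
    RECEPTORS,
    DrugProfile,
    SynapseParams,
    functional_concentration,
    receptor_activation,
    receptor_occupancy,
    steady_state_level,
)


@dataclass(frozen=True)
class PathologyParams:
    """Schizophrenia disease parameters applied on top of the healthy circuit."""

    striatal_da_gain: float = 1.5  # hyperdopaminergic striatum, multiplier > 1
    cortical_da_gain: float = 0.7  # hypodopaminergic cortex, multiplier < 1
    glu_deficit: float = 0.2  # fractional loss of cortical glutamatergic drive
    gaba_deficit: float = 0.2  # fractional loss of cortical GABAergic inhibition
    noise_gain: float = 1.3  # background noise multiplier

    def __post_init__(self) -> None:
        if self.striatal_da_gain <= 1.0:
            raise ValueError("striatal_da_gain must be > 1 (hyperdopaminergic)")
        if not 0.0 < self.cortical_da_gain < 1.0:
            raise ValueError("cortical_da_gain must be in (0, 1) (hypodopaminergic)")
        for name in ("glu_deficit", "gaba_deficit"):
            if not 0.0 <= getattr(self, name) < 1.0:
                raise ValueError(f"{name} must be in [0, 1)")
        if self.noise_gain < 1.0:
            raise ValueError("noise_gain must be >= 1")


HEALTHY = PathologyParams.__new__(PathologyParams)  # bypass validation sentinel
object.__setattr__(HEALTHY, "striatal_da_gain", 1.0)
object.__setattr__(HEALTHY, "cortical_da_gain", 1.0)
object.__setattr__(HEALTHY, "glu_deficit", 0.0)
object.__setattr__(HEALTHY, "gaba_deficit", 0.0)
object.__setattr__(HEALTHY, "noise_gain", 1.0)


#: Endogenous-ligand affinity (Ki, nM) at each receptor.  Calibration
#: conveniences consistent with the order of magnitude of published values;
#: all config-exposed, none are printed study data.
DEFAULT_LIGAND_KI: dict[str, float] = {
    "D1": 1600.0,
    "D2": 160.0,
    "D4": 30.0,
    "5HT1A": 100.0,
    "5HT2A": 300.0,
    "5HT3": 200.0,
    "5HT6": 150.0,
    "M1": 400.0,
    "alpha1": 300.0,
    "alpha2": 80.0,
    "H1": 600.0,
}

#: Tonic levels (nM) of the modulators without a genotype hook.
DEFAULT_TONIC_LEVELS: dict[str, float] = {
    "acetylcholine": 50.0,
    "norepinephrine": 40.0,
    "histamine": 30.0,
}


@dataclass(frozen=True)
class SynapseConfig:
    """Default synapse parameterisation for the genotype-sensitive ligands.

    Quanta are scaled so that the healthy reference basal levels are
    100 nM-equivalents of striatal dopamine, 30 nM cortical dopamine and
    50 nM serotonin at the reference heterozygote (tau 130 / 75 ms).
    """

    firing_rate: float = 5.0  # Hz, tonic presynaptic rate for all ligands
    striatal_da_tau: float = 100.0  # ms, COMT-independent
    striatal_da_basal: float = 100.0  # nM at healthy reference
    cortical_da_basal: float = 30.0  # nM at healthy reference heterozygote
    serotonin_basal: float = 50.0  # nM at reference heterozygote

    def striatal_dopamine(self, pathology: PathologyParams = HEALTHY) -> SynapseParams:
        quantum = self.striatal_da_basal * math.log(2.0) / (
            self.firing_rate * self.striatal_da_tau / 1000.0
        )
        return SynapseParams(
            ligand="dopamine",
            firing_rate=self.firing_rate * pathology.striatal_da_gain,
            quantum=quantum,
            half_life=self.striatal_da_tau,
        )

    def cortical_dopamine(
        self, effects: GenotypeEffects, pathology: PathologyParams = HEALTHY
    ) -> SynapseParams:
        ref_tau = genotype_effects(REFERENCE_GENOTYPE).tau_da_cortical
        quantum = self.cortical_da_basal * math.log(2.0) / (
            self.firing_rate * ref_tau / 1000.0
        )
        return SynapseParams(
            ligand="dopamine",
            firing_rate=self.firing_rate * pathology.cortical_da_gain,
            quantum=quantum,
            half_life=effects.tau_da_cortical,
        )

    def serotonin(self, effects: GenotypeEffects) -> SynapseParams:
        ref_tau = genotype_effects(REFERENCE_GENOTYPE).tau_5ht
        quantum = self.serotonin_basal * math.log(2.0) / (
            self.firing_rate * ref_tau / 1000.0
        )
        return SynapseParams(
            ligand="serotonin",
            firing_rate=self.firing_rate,
            quantum=quantum,
            half_life=effects.tau_5ht,
        )


DEFAULT_SYNAPSES = SynapseConfig()


def basal_ligand_levels(
    effects: GenotypeEffects,
    pathology: PathologyParams = PathologyParams(),
    synapses: SynapseConfig = DEFAULT_SYNAPSES,
) -> dict[tuple[str, str], float]:
    """Basal neurotransmitter levels (nM) keyed by (ligand, compartment)."""
    levels = {
        ("dopamine", "striatal"): steady_state_level(synapses.striatal_dopamine(pathology)),
        ("dopamine", "cortical"): steady_state_level(
            synapses.cortical_dopamine(effects, pathology)
        ),
    }
    sero = steady_state_level(synapses.serotonin(effects))
    levels[("serotonin", "striatal")] = sero
    levels[("serotonin", "cortical")] = sero
    for ligand, level in DEFAULT_TONIC_LEVELS.items():
        levels[(ligand, "striatal")] = level
        levels[(ligand, "cortical")] = level
    return levels


def drug_concentration(
    drug: DrugProfile | None,
    dose_mg: float,
    pathology: PathologyParams = PathologyParams(),
    synapses: SynapseConfig = DEFAULT_SYNAPSES,
) -> float:
    """Functional drug concentration (nM) at ``dose_mg``; 0 for placebo.

    Anchored on striatal D2 occupancy with the pathological (patient-state)
    striatal dopamine competition, matching the PET displacement setting in
    which clinical occupancy-versus-dose data are collected.
    """
    if drug is None or dose_mg == 0.0:
        return 0.0
    return functional_concentration(
        drug, dose_mg, synapses.striatal_dopamine(pathology), DEFAULT_LIGAND_KI["D2"]
    )


def receptor_signals(
    drug: DrugProfile | None,
    dose_mg: float,
    effects: GenotypeEffects,
    pathology: PathologyParams = PathologyParams(),
    compartment: str = "striatal",
    synapses: SynapseConfig = DEFAULT_SYNAPSES,
) -> dict[str, float]:
    """Activation signal per receptor for one compartment.

    The DRD2 Taq1A expression scale applies to striatal D2 only; every other
    receptor uses expression scale 1.  Receptors a drug does not bind are
    evaluated at endogenous tone alone.
    """
    if compartment not in ("striatal", "cortical"):
        raise ValueError(f"unknown compartment {compartment!r}")
    conc = drug_concentration(drug, dose_mg, pathology, synapses)
    levels = basal_ligand_levels(effects, pathology, synapses)
    out: dict[str, float] = {}
    for receptor, (where, ligand) in RECEPTORS.items():
        if where != "both" and where != compartment:
            continue
        occ = receptor_occupancy(
            ligand_conc=levels[(ligand, compartment)],
            drug_conc=conc,
            ki_ligand=DEFAULT_LIGAND_KI[receptor],
            ki_drug=drug.ki(receptor) if drug is not None else math.inf,
        )
        scale = effects.d2r_scale if (receptor == "D2" and compartment == "striatal") else 1.0
        alpha = drug.efficacy(receptor) if drug is not None else 0.0
        out[receptor] = receptor_activation(occ, alpha, scale)
    return out


@lru_cache(maxsize=8)
def _reference_signals_cached(
    pathology: PathologyParams, compartment: str
) -> Mapping[str, float]:
    effects = genotype_effects(REFERENCE_GENOTYPE)
    return receptor_signals(None, 0.0, effects, pathology, compartment)


def reference_signals(
    pathology: PathologyParams = PathologyParams(), compartment: str = "striatal"
) -> Mapping[str, float]:
    """Signals of the untreated reference heterozygote (calibration baseline)."""
    return dict(_reference_signals_cached(pathology, compartment))
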