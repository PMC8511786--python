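"""Synaptic neurotransmitter dynamics and competitive receptor pharmacology.

The receptor model treats every postsynaptic receptor as a single
Hill-coefficient-1 binding site at which the endogenous neurotransmitter and
the active moiety of a drug compete at equilibrium.  Synaptic neurotransmitter
levels follow a pulsatile release / first-order clearance model whose
steady-state mean is ``baseline + rate * quantum * half_life / ln 2``; genotype
effects enter exclusively through the clearance half-life.

Clinical doses are converted to intrasynaptic functional concentrations by
inverting simulated PET displacement: the concentration assigned to a dose is
the one whose simulated D2 occupancy (with striatal dopamine competition)
reproduces a published-style occupancy-versus-dose anchor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

LN2 = math.log(2.0)

#: Receptors implemented in the circuit models, with the compartment where
#: they act and their endogenous ligand.
RECEPTORS: dict[str, tuple[str, str]] = {
    # name: (compartment, endogenous ligand)
    "D1": ("both", "dopamine"),
    "D2": ("striatal", "dopamine"),
    "D4": ("cortical", "dopamine"),
    "5HT1A": ("cortical", "serotonin"),
    "5HT2A": ("cortical", "serotonin"),
    "5HT3": ("cortical", "serotonin"),
    "5HT6": ("cortical", "serotonin"),
    "M1": ("cortical", "acetylcholine"),
    "alpha1": ("both", "norepinephrine"),
    "alpha2": ("cortical", "norepinephrine"),
    "H1": ("cortical", "histamine"),
}


@dataclass(frozen=True)
class ReceptorSpec:
    """A postsynaptic receptor site.

    Parameters
    ----------
    name : str
        Receptor identifier (``"D2"``, ``"5HT2A"``, ...).
    compartment : {"cortical", "striatal", "both"}
        Where the receptor participates in circuit coupling.
    endogenous_ligand : str
        The neurotransmitter competing with drug at this site.
    expression_scale : float
        Dimensionless receptor-density multiplier (>= 0).  Striatal D2
        expression carries the DRD2 Taq1A genotype effect here.
    """

    name: str
    compartment: str = "both"
    endogenous_ligand: str = "dopamine"
    expression_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.expression_scale < 0:
            raise ValueError("expression_scale must be >= 0")
        if self.compartment not in ("cortical", "striatal", "both"):
            raise ValueError(f"unknown compartment {self.compartment!r}")


@dataclass(frozen=True)
class SynapseParams:
    """Pulsatile-release synapse with first-order clearance.

    ``firing_rate`` is the tonic presynaptic rate in Hz, ``quantum`` the
    concentration increment (nM) per release event, ``half_life`` the
    clearance half-life in ms and ``baseline`` a release-independent floor
    (nM).
    """

    ligand: str
    firing_rate: float
    quantum: float
    half_life: float  # ms
    baseline: float = 0.0

    def __post_init__(self) -> None:
        if self.half_life <= 0:
            raise ValueError("half_life must be > 0")
        if self.firing_rate < 0 or self.quantum < 0 or self.baseline < 0:
            raise ValueError("firing_rate, quantum and baseline must be >= 0")


@dataclass(frozen=True)
class OccupancySolution:
    """Equilibrium occupancy fractions of a receptor population."""

    occ_ligand: float
    occ_drug: float
    occ_free: float
    signal: float | None = None

    def __post_init__(self) -> None:
        total = self.occ_ligand + self.occ_drug + self.occ_free
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"occupancies must sum to 1, got {total!r}")
        for occ in (self.occ_ligand, self.occ_drug, self.occ_free):
            if not (-1e-12 <= occ <= 1 + 1e-12):
                raise ValueError("occupancy fraction outside [0, 1]")


@dataclass
class DrugProfile:
    """Receptor pharmacology of one antipsychotic.

    ``affinities`` maps receptor name to Ki (nM); ``efficacies`` maps receptor
    name to intrinsic efficacy alpha in [0, 1] (0 = neutral antagonist,
    1 = full agonist; missing receptors default to 0).
    ``occupancy_anchors`` are (dose mg, striatal D2 occupancy fraction) pairs
    used to convert dose into functional concentration.
    """

    name: str
    standard_dose: float  # mg
    affinities: Mapping[str, float]
    efficacies: Mapping[str, float] = field(default_factory=dict)
    occupancy_anchors: Sequence[tuple[float, float]] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.standard_dose <= 0:
            raise ValueError("standard_dose must be > 0")
        for rec, ki in self.affinities.items():
            if ki <= 0:
                raise ValueError(f"Ki must be > 0 for {rec}")
        for rec, alpha in self.efficacies.items():
            if not 0.0 <= alpha <= 1.0:
                raise ValueError(f"efficacy must be in [0, 1] for {rec}")
        anchors = [(float(d), float(o)) for d, o in self.occupancy_anchors]
        doses = [d for d, _ in anchors]
        occs = [o for _, o in anchors]
        if any(d2 <= d1 for d1, d2 in zip(doses, doses[1:])):
            raise ValueError("anchor doses must be strictly increasing")
        if any(o2 < o1 for o1, o2 in zip(occs, occs[1:])):
            raise ValueError("anchor occupancies must be non-decreasing")
        self.occupancy_anchors = tuple(anchors)

    def efficacy(self, receptor: str) -> float:
        return float(self.efficacies.get(receptor, 0.0))

    def ki(self, receptor: str) -> float:
        """Ki at ``receptor`` in nM; +inf when the drug does not bind it."""
        return float(self.affinities.get(receptor, math.inf))


def steady_state_level(synapse: SynapseParams) -> float:
    """Mean synaptic concentration (nM) under tonic firing.

    Closed form of the pulsatile-release/first-order-clearance model:
    ``baseline + firing_rate * quantum * half_life / ln 2`` with the half-life
    converted to seconds.
    """
    tau_s = synapse.half_life / 1000.0
    return synapse.baseline + synapse.firing_rate * synapse.quantum * tau_s / LN2


def neurotransmitter_trace(
    synapse: SynapseParams,
    firing_times: Sequence[float],
    duration: float,
    dt: float,
    initial: float | None = None,
) -> np.ndarray:
    """Concentration time series (nM) for explicit release events.

    Between releases the concentration relaxes exponentially toward
    ``baseline`` with the configured half-life; at each release it jumps by
    ``quantum``.  ``dt`` must resolve the decay (< half_life / 5).
    """
    if dt <= 0 or duration <= 0:
        raise ValueError("dt and duration must be > 0")
    tau_s = synapse.half_life / 1000.0
    if dt >= tau_s / 5.0:
        raise ValueError(
            f"dt={dt} s under-resolves the decay (need dt < half_life/5 = {tau_s / 5.0} s)"
        )
    times = np.asarray(firing_times, dtype=float)
    if times.size and (times.min() < 0 or times.max() > duration):
        raise ValueError("firing_times must lie within [0, duration]")
    n = int(round(duration / dt)) + 1
    decay = math.exp(-LN2 * dt / tau_s)
    counts = np.zeros(n)
    idx = np.clip((times / dt).astype(int), 0, n - 1)
    np.add.at(counts, idx, 1.0)
    trace = np.empty(n)
    c = synapse.baseline if initial is None else float(initial)
    for i in range(n):
        c = synapse.baseline + (c - synapse.baseline) * decay
        c += synapse.quantum * counts[i]
        trace[i] = c
    return trace


def receptor_occupancy(
    ligand_conc: float,
    drug_conc: float,
    ki_ligand: float,
    ki_drug: float,
) -> OccupancySolution:
    """Competitive-equilibrium occupancy of ligand vs. drug at one receptor.

    ``occ_drug = (D/Kd) / (1 + D/Kd + L/KL)`` and analogously for the ligand;
    the free fraction makes the three sum to 1.
    """
    if ligand_conc < 0 or drug_conc < 0:
        raise ValueError("concentrations must be >= 0")
    if ki_ligand <= 0 or ki_drug <= 0:
        raise ValueError("Ki values must be > 0")
    rl = ligand_conc / ki_ligand
    rd = drug_conc / ki_drug if math.isfinite(ki_drug) else 0.0
    denom = 1.0 + rl + rd
    return OccupancySolution(
        occ_ligand=rl / denom,
        occ_drug=rd / denom,
        occ_free=1.0 / denom,
    )


def receptor_activation(
    occ: OccupancySolution,
    efficacy_drug: float,
    expression_scale: float = 1.0,
) -> float:
    """Circuit-coupling signal from an occupancy solution.

    ``signal = (occ_ligand + occ_drug * efficacy) * expression_scale``;
    the endogenous ligand is a full agonist by definition.
    """
    if not 0.0 <= efficacy_drug <= 1.0:
        raise ValueError("efficacy must be in [0, 1]")
    if expression_scale < 0:
        raise ValueError("expression_scale must be >= 0")
    return (occ.occ_ligand + occ.occ_drug * efficacy_drug) * expression_scale


def _specific_binding(ligand_conc: float, ki_ligand: float, drug_conc: float, ki_drug: float) -> float:
    """Tracer specific binding at the trace-concentration limit (arbitrary units)."""
    rd = drug_conc / ki_drug if math.isfinite(ki_drug) else 0.0
    return 1.0 / (1.0 + ligand_conc / ki_ligand + rd)


def simulate_pet_displacement(
    tracer_ki: float,
    synapse: SynapseParams,
    ligand_ki: float,
    drug_conc: float = 0.0,
    drug_ki: float = math.inf,
    reference_synapse: SynapseParams | None = None,
    reference_drug_conc: float = 0.0,
    reference_drug_ki: float = math.inf,
) -> float:
    """Fractional change in tracer specific binding vs. a reference condition.

    The radiotracer is at trace concentration (no self-competition), so its
    specific binding is proportional to ``1 / (1 + L/KL + D/Kd)``; the tracer
    Ki cancels in the fractional change but is kept for interface symmetry.
    Raising either the basal ligand level or the drug concentration displaces
    the tracer (negative change).
    """
    if tracer_ki <= 0:
        raise ValueError("tracer_ki must be > 0")
    if drug_conc < 0 or reference_drug_conc < 0:
        raise ValueError("drug concentrations must be >= 0")
    ref_syn = synapse if reference_synapse is None else reference_synapse
    l_test = steady_state_level(synapse)
    l_ref = steady_state_level(ref_syn)
    b_test = _specific_binding(l_test, ligand_ki, drug_conc, drug_ki)
    b_ref = _specific_binding(l_ref, ligand_ki, reference_drug_conc, reference_drug_ki)
    if b_ref == 0:
        raise ZeroDivisionError("degenerate reference: zero reference binding")
    return (b_test - b_ref) / b_ref


def occupancy_to_concentration(
    occupancy: float, ki_drug: float, ligand_conc: float, ki_ligand: float
) -> float:
    """Invert the competitive binding closed form for the drug concentration."""
    if not 0.0 <= occupancy < 1.0:
        raise ValueError(f"infeasible anchor occupancy {occupancy!r} (must be in [0, 1))")
    return ki_drug * (1.0 + ligand_conc / ki_ligand) * occupancy / (1.0 - occupancy)


def functional_concentration(
    drug: DrugProfile,
    dose: float,
    synapse: SynapseParams,
    ligand_ki: float,
) -> float:
    """Intrasynaptic functional concentration (nM) of a drug at ``dose`` mg.

    Each occupancy anchor is inverted through the competitive-binding closed
    form (with striatal ligand competition from ``synapse``) to an implied
    concentration; log-concentration is interpolated linearly in log-dose
    between anchors, with proportional (conc ~ dose) extrapolation beyond the
    anchor range.  Strictly increasing in dose whenever the anchor
    occupancies strictly increase.
    """
    if dose <= 0:
        raise ValueError("dose must be > 0")
    if not drug.occupancy_anchors:
        raise ValueError(f"{drug.name}: no occupancy anchors configured")
    ki_d2 = drug.ki("D2")
    if not math.isfinite(ki_d2):
        raise ValueError(f"{drug.name}: D2 affinity required for dose anchoring")
    ligand_conc = steady_state_level(synapse)
    anchor_doses = np.array([d for d, _ in drug.occupancy_anchors])
    anchor_concs = np.array(
        [
            occupancy_to_concentration(occ, ki_d2, ligand_conc, ligand_ki)
            for _, occ in drug.occupancy_anchors
        ]
    )
    if dose <= anchor_doses[0]:
        return float(anchor_concs[0] * dose / anchor_doses[0])
    if dose >= anchor_doses[-1]:
        return float(anchor_concs[-1] * dose / anchor_doses[-1])
    log_conc = np.interp(math.log(dose), np.log(anchor_doses), np.log(anchor_concs))
    return float(math.exp(log_conc))
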