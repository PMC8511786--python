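"""Prefrontal working-memory network and the 2-back accuracy readout.

The cognitive surrogate is a cortical network of 80 pyramidal glutamatergic
units and 30 GABAergic interneurons.  A subset of the pyramidal population
carries slow (NMDA-like) recurrent excitation: a brief stimulus at t = 2 s
ignites persistent activity in that subset, and spike-frequency adaptation
plus background noise eventually extinguish it.  The time the memory subset
stays above a detection threshold after stimulus offset is the working-memory
span, mapped through a saturating logistic calibration onto 2-back accuracy.

Neuromodulator hooks (all config-exposed gains on signals computed at the
cortical compartment): D1 raises pyramidal excitability, D4 scales the
recurrent conductance, 5-HT3 and 5-HT6 activation destabilise the network by
speeding adaptation, 5-HT1A agonism and alpha2 activation improve
signal-to-noise, 5-HT2A activation adds noise, and M1 supports excitability.
Striatal D2 expression (DRD2 Taq1A) has no hook here by design, so cognition
outputs are bit-identical across DRD2 genotypes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .genotypes import GenotypeEffects
from .network import Connection, LifNetwork, PopulationSpec
from .signals import PathologyParams, reference_signals

__all__ = [
    "CorticalNetworkConfig",
    "StimulusProtocol",
    "ActivityTrace",
    "AccuracyCalibration",
    "run_working_memory_trial",
    "working_memory_span",
    "span_to_accuracy",
]

#: Receptors with a coupling hook in the cortical network.
CORTICAL_MODULATORS = ("D1", "D4", "5HT1A", "5HT2A", "5HT3", "5HT6", "M1", "alpha2")


@dataclass(frozen=True)
class StimulusProtocol:
    """Brief current injection into the memory subset."""

    onset: float = 2.0  # s
    width_ms: float = 50.0
    amplitude: float = 2.5

    def __post_init__(self) -> None:
        if self.width_ms <= 0:
            raise ValueError("stimulus width must be > 0")
        if self.onset < 0:
            raise ValueError("stimulus onset must be >= 0")

    @property
    def offset(self) -> float:
        return self.onset + self.width_ms / 1000.0


@dataclass(frozen=True)
class CorticalNetworkConfig:
    """80 pyramidal / 30 interneuron prefrontal network with modulator hooks."""

    n_pyramidal: int = 80
    n_interneuron: int = 30
    n_memory: int = 20  # stimulated subset of the pyramidal population
    dt_ms: float = 1.0
    duration_s: float = 10.0
    w_recurrent: float = 6.8  # slow recurrent excitation within the memory subset
    tau_recurrent_ms: float = 80.0
    mem_bias: float = 0.75
    bg_bias: float = 0.8
    inh_bias: float = 0.3
    noise_sd: float = 0.12
    adapt_increment: float = 0.008
    adapt_tau_ms: float = 8000.0
    bin_ms: float = 10.0
    couplings: Mapping[str, float] = field(
        default_factory=lambda: {
            # basal cortical D1 occupancy is small (~0.01), so the excitability
            # coupling is large to make COMT-driven tone changes count
            "D1": 40.0,      # pyramidal excitability per unit cortical D1 signal
            "D4": 1.0,       # recurrent conductance scale
            "5HT1A": 1.0,    # noise reduction (signal-to-noise)
            "5HT2A": 1.5,    # noise increase
            "5HT3": 3.0,     # adaptation speed-up (destabilising)
            "5HT6": 3.0,     # adaptation speed-up (destabilising)
            "M1": 1.0,       # cholinergic excitability support
            "alpha2": 0.5,   # noise reduction
        }
    )
    reference_signals: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if self.n_memory > self.n_pyramidal:
            raise ValueError("memory subset cannot exceed the pyramidal population")


@dataclass(frozen=True)
class ActivityTrace:
    """Memory-subset population rate (Hz per unit) at fixed resolution."""

    times: np.ndarray  # bin centres, s
    activity: np.ndarray  # Hz
    stim_offset: float  # s
    duration: float  # s


def run_working_memory_trial(
    config: CorticalNetworkConfig,
    stim: StimulusProtocol,
    drug_signals: Mapping[str, float],
    effects: GenotypeEffects,
    seed: int,
    pathology: PathologyParams = PathologyParams(),
) -> ActivityTrace:
    """Run one delayed working-memory trial; deterministic per seed.

    ``drug_signals`` are cortical-compartment signals; genotype enters through
    the cortical dopamine and serotonin basal tone already folded into them
    (COMT and 5-HTTLPR only — there is deliberately no striatal D2 hook).
    """
    if stim.offset >= config.duration_s:
        raise ValueError("stimulus extends beyond the simulation duration")
    ref = config.reference_signals
    if ref is None:
        ref = reference_signals(pathology, "cortical")
    c = config.couplings

    def delta(receptor: str) -> float:
        return drug_signals[receptor] - ref[receptor]

    g_excit = math.exp(c["D1"] * delta("D1") + c["M1"] * delta("M1"))
    g_rec = math.exp(c["D4"] * delta("D4"))
    g_adapt = math.exp(c["5HT3"] * delta("5HT3") + c["5HT6"] * delta("5HT6"))
    g_noise = math.exp(
        c["5HT2A"] * delta("5HT2A")
        - c["5HT1A"] * delta("5HT1A")
        - c["alpha2"] * delta("alpha2")
    )

    glu = 1.0 - pathology.glu_deficit
    gaba = 1.0 - pathology.gaba_deficit
    noise = config.noise_sd * pathology.noise_gain * g_noise

    n_bg = config.n_pyramidal - config.n_memory
    pops = [
        PopulationSpec(
            "mem", config.n_memory, tau_m=20.0, bias=config.mem_bias * glu * g_excit,
            noise_sd=noise, adapt_increment=config.adapt_increment * g_adapt,
            adapt_tau_ms=config.adapt_tau_ms,
        ),
        PopulationSpec("bg_e", max(n_bg, 1), tau_m=15.0, bias=config.bg_bias * glu,
                       noise_sd=noise),
        PopulationSpec("inh", config.n_interneuron, tau_m=10.0, bias=config.inh_bias,
                       noise_sd=0.1),
    ]
    conns = [
        Connection("mem", "mem", config.w_recurrent * glu * g_rec, config.tau_recurrent_ms),
        Connection("mem", "inh", 0.6, 5.0),
        Connection("bg_e", "inh", 0.4, 5.0),
        Connection("inh", "mem", -0.5 * gaba, 8.0),
        Connection("inh", "bg_e", -0.5 * gaba, 8.0),
    ]
    net = LifNetwork(pops, conns, dt_ms=config.dt_ms)
    pulses = {"mem": [(stim.onset, stim.offset, stim.amplitude)]} if stim.amplitude else None
    res = net.run(config.duration_s, seed=seed, record=("mem",), pulses=pulses)

    spikes = res.spikes["mem"]  # [steps, n]
    bin_steps = int(round(config.bin_ms / config.dt_ms))
    n_bins = spikes.shape[0] // bin_steps
    counts = spikes[: n_bins * bin_steps].reshape(n_bins, bin_steps, -1).sum(axis=(1, 2))
    rate = counts / (config.n_memory * config.bin_ms / 1000.0)
    times = (np.arange(n_bins) + 0.5) * config.bin_ms / 1000.0
    return ActivityTrace(
        times=times, activity=rate, stim_offset=stim.offset, duration=config.duration_s
    )


def working_memory_span(trace: ActivityTrace, threshold: float = 10.0) -> float:
    """Seconds of suprathreshold memory activity after stimulus offset.

    Span runs from stimulus offset until activity first stays below
    ``threshold`` for a sustained 100 ms; 0 if activity never exceeds the
    threshold after offset, capped at ``duration - offset`` if it never
    falls.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    mask = trace.times >= trace.stim_offset
    times = trace.times[mask]
    act = trace.activity[mask]
    if times.size == 0:
        raise ValueError("trace does not cover the post-stimulus period")
    if not (act >= threshold).any():
        return 0.0
    dt = float(np.median(np.diff(times))) if times.size > 1 else 0.01
    sustain = max(int(round(0.1 / dt)), 1)
    below = act < threshold
    run = 0
    for i, b in enumerate(below):
        run = run + 1 if b else 0
        if run >= sustain:
            first = times[i - sustain + 1] - dt / 2.0  # leading edge of the drop
            return max(float(first - trace.stim_offset), 0.0)
    return float(trace.duration - trace.stim_offset)


@dataclass(frozen=True)
class AccuracyCalibration:
    """Saturating map from working-memory span (s) to 2-back % correct.

    Logistic between a chance floor and a ceiling of 100%; the schizophrenia
    patient state is represented as an accuracy offset of
    ``patient_offset_sd`` standard deviations below the normal mean
    (applied only when ``as_patient`` is set, clamped at the floor).
    """

    midpoint_s: float = 3.0
    steepness: float = 0.8
    floor: float = 50.0
    ceiling: float = 100.0
    patient_offset_sd: float = 1.5
    normal_sd_pct: float = 7.0
    as_patient: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.floor < self.ceiling <= 100.0:
            raise ValueError("need 0 <= floor < ceiling <= 100")
        if self.steepness <= 0:
            raise ValueError("steepness must be > 0")


def span_to_accuracy(span: float, cal: AccuracyCalibration = AccuracyCalibration()) -> float:
    """2-back accuracy (%) for a working-memory span; monotone and bounded."""
    if span < 0:
        raise ValueError("span must be >= 0")
    logistic = 1.0 / (1.0 + math.exp(-cal.steepness * (span - cal.midpoint_s)))
    acc = cal.floor + (cal.ceiling - cal.floor) * logistic
    if cal.as_patient:
        acc -= cal.patient_offset_sd * cal.normal_sd_pct
    return float(min(max(acc, cal.floor), cal.ceiling))
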