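"""Minimal vectorised leaky-integrate-and-fire population network.

All circuit surrogates in this package are built on the same engine: a set of
named populations of LIF units (membrane time constant ``tau_m``, unit
threshold 1, reset 0, absolute refractory period) coupled through
population-level exponential synaptic traces.  A connection's trace integrates
the presynaptic population's mean spike count with its synaptic time constant
and is normalised so that its steady state equals the presynaptic rate in
units of 100 Hz; the current delivered to every postsynaptic unit is
``weight * trace`` (so ``weight`` is the current produced by a 100 Hz
presynaptic population, whatever the synaptic kinetics).  Per-unit Gaussian current noise and a global drive scale
on the bias currents complete the input.

The engine is deterministic given (structure, seed): with zero noise and zero
drive every population stays silent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np


@dataclass(frozen=True)
class PopulationSpec:
    """One LIF population.

    ``bias`` is a constant input current multiplied by the network drive
    scale; ``adapt_increment``/``adapt_tau_ms`` configure an optional
    spike-frequency adaptation current (0 disables it).
    """

    name: str
    n: int
    tau_m: float  # ms
    bias: float = 0.0
    noise_sd: float = 0.0
    refractory_ms: float = 2.0
    adapt_increment: float = 0.0
    adapt_tau_ms: float = 400.0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("population size must be >= 1")
        if self.tau_m <= 0:
            raise ValueError("tau_m must be > 0")


@dataclass(frozen=True)
class Connection:
    """Population-to-population synapse with exponential trace kinetics."""

    pre: str
    post: str
    weight: float
    tau_s: float  # ms

    def __post_init__(self) -> None:
        if self.tau_s <= 0:
            raise ValueError("tau_s must be > 0")
        if not math.isfinite(self.weight):
            raise ValueError("weight must be finite")


@dataclass
class SimResult:
    """Output of one network run (warm-up period already discarded)."""

    dt_ms: float
    duration_s: float
    spikes: dict[str, np.ndarray]  # name -> bool array [steps, n]
    lfp: np.ndarray | None = None  # summed |synaptic current| into lfp target


class LifNetwork:
    """A fixed network structure that can be run repeatedly with different seeds."""

    def __init__(
        self,
        populations: Sequence[PopulationSpec],
        connections: Sequence[Connection],
        dt_ms: float = 1.0,
    ) -> None:
        if dt_ms <= 0 or dt_ms > 1.0:
            raise ValueError("integration step must be in (0, 1] ms")
        names = [p.name for p in populations]
        if len(set(names)) != len(names):
            raise ValueError("population names must be unique")
        known = set(names)
        for c in connections:
            if c.pre not in known or c.post not in known:
                raise ValueError(f"connection references unknown population: {c.pre}->{c.post}")
        self.populations = list(populations)
        self.connections = list(connections)
        self.dt_ms = float(dt_ms)
        self._index = {p.name: i for i, p in enumerate(self.populations)}

    def run(
        self,
        duration_s: float,
        seed: int,
        drive: float = 1.0,
        record: Sequence[str] = (),
        lfp_into: str | None = None,
        pulses: Mapping[str, Sequence[tuple[float, float, float]]] | None = None,
        warmup_s: float = 0.0,
    ) -> SimResult:
        """Integrate the network and return spikes of ``record`` populations.

        ``pulses`` maps population name to (t_start s, t_end s, amplitude)
        current injections.  ``lfp_into`` selects a population whose total
        rectified synaptic input current is recorded as a field-potential
        proxy.  The first ``warmup_s`` seconds are simulated but discarded.
        """
        if duration_s <= 0:
            raise ValueError("duration_s must be > 0")
        dt = self.dt_ms
        n_total = int(round((warmup_s + duration_s) * 1000.0 / dt))
        n_warm = int(round(warmup_s * 1000.0 / dt))
        rng = np.random.default_rng(seed)

        pops = self.populations
        npop = len(pops)
        sizes = np.array([p.n for p in pops])
        offsets = np.concatenate([[0], np.cumsum(sizes)])  # unit-slab boundaries
        n_units = int(offsets[-1])
        unit_pop = np.repeat(np.arange(npop), sizes)  # pop index of each unit
        decay_v = (dt / np.array([p.tau_m for p in pops]))[unit_pop]
        bias = (np.array([p.bias for p in pops]) * drive)
        noise_u = np.array([p.noise_sd for p in pops])[unit_pop]
        any_noise = bool((noise_u > 0).any())
        refrac_steps = np.array([int(round(p.refractory_ms / dt)) for p in pops])[unit_pop]
        adapt_b = np.array([p.adapt_increment for p in pops])[unit_pop]
        adapt_decay = np.array([math.exp(-dt / p.adapt_tau_ms) for p in pops])[unit_pop]
        any_adapt = bool((adapt_b > 0).any())

        v = np.zeros(n_units)
        a = np.zeros(n_units)
        ref = np.zeros(n_units, dtype=int)
        pop_rate = np.zeros(npop)  # mean spike count per unit, previous step

        conns = self.connections
        trace = np.zeros(len(conns))
        conn_decay = np.array([math.exp(-dt / c.tau_s) for c in conns])
        # steady-state trace = presynaptic rate / 100 Hz, independent of tau_s
        conn_norm = np.array([10.0 / c.tau_s for c in conns])
        weights = np.array([c.weight for c in conns])
        pre_idx = np.array([self._index[c.pre] for c in conns], dtype=int)
        post_idx = np.array([self._index[c.post] for c in conns], dtype=int)
        lfp_conns = (
            np.array([], dtype=int)
            if lfp_into is None
            else np.nonzero(post_idx == self._index[lfp_into])[0]
        )

        pulse_spec: list[list[tuple[int, int, float]]] = [[] for _ in pops]
        if pulses:
            for name, plist in pulses.items():
                for t0, t1, amp in plist:
                    if not 0.0 <= t0 < t1 <= warmup_s + duration_s:
                        raise ValueError(f"pulse ({t0}, {t1}) outside simulation window")
                    pulse_spec[self._index[name]].append(
                        (int(round(t0 * 1000.0 / dt)), int(round(t1 * 1000.0 / dt)), amp)
                    )

        rec_slices = {name: slice(offsets[self._index[name]], offsets[self._index[name] + 1])
                      for name in record}
        rec_spikes = {
            name: np.zeros((n_total - n_warm, pops[self._index[name]].n), dtype=bool)
            for name in record
        }
        lfp = np.zeros(n_total - n_warm) if lfp_into is not None else None
        lfp_n = sizes[post_idx[lfp_conns[0]]] if lfp_conns.size else 0
        w_abs_lfp = np.abs(weights[lfp_conns])

        for step in range(n_total):
            trace *= conn_decay
            trace += conn_norm * pop_rate[pre_idx]
            syn_current = np.bincount(post_idx, weights=weights * trace, minlength=npop)
            if lfp is not None and step >= n_warm and lfp_conns.size:
                lfp[step - n_warm] = lfp_n * float(w_abs_lfp @ trace[lfp_conns])

            current = syn_current + bias
            for i, plist in enumerate(pulse_spec):
                for t0, t1, amp in plist:
                    if t0 <= step < t1:
                        current[i] += amp
            inp = current[unit_pop] - a
            if any_noise:
                inp += noise_u * rng.standard_normal(n_units)
            v += decay_v * (-v + inp)
            refractory = ref > 0
            v[refractory] = 0.0
            ref[refractory] -= 1
            fired = (v >= 1.0) & ~refractory
            v[fired] = 0.0
            ref[fired] = refrac_steps[fired]
            if any_adapt:
                a *= adapt_decay
                a[fired] += adapt_b[fired]
            pop_rate = np.add.reduceat(fired, offsets[:-1]) / sizes

            if step >= n_warm:
                for name, sl in rec_slices.items():
                    rec_spikes[name][step - n_warm] = fired[sl]

        return SimResult(dt_ms=dt, duration_s=duration_s, spikes=rec_spikes, lfp=lfp)
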