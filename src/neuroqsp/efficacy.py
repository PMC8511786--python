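"""Associative cortico-striatal-thalamo-cortical loop and the efficacy readout.

A small LIF surrogate of the closed basal-ganglia loop: cortical
excitatory/inhibitory populations drive D1-expressing (direct pathway) and
D2-expressing (indirect pathway) medium spiny neurons, which converge with
opposite signs on an internal-pallidum population gating thalamus; the
thalamic reticular nucleus (TRN) is the readout.  Dopamine signals couple as
gain modulation — the D1 signal scales direct-pathway excitability up and the
D2 signal scales indirect-pathway excitability down — so antipsychotic D2
antagonism re-engages the indirect pathway that the hyperdopaminergic striatum
has silenced.

The clinical endpoint is the Shannon entropy of binary TRN spike words
(a signal-bandwidth measure): the relative entropy change of a treated run
against the untreated reference is mapped affinely onto change in PANSS Total
through configurable calibration anchors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .genotypes import GenotypeEffects
from .network import Connection, LifNetwork, PopulationSpec, SimResult
from .signals import PathologyParams, reference_signals

__all__ = [
    "PathologyParams",
    "LoopConfig",
    "SpikeRaster",
    "PanssCalibration",
    "run_cstc_loop",
    "shannon_entropy",
    "entropy_to_delta_panss",
    "dose_response_slope",
]


@dataclass(frozen=True)
class LoopConfig:
    """Structure and couplings of the associative loop surrogate.

    Population sizes default to the documented small-network realisation
    (40 cortical E, 10 cortical I, 20 D1-MSN, 20 D2-MSN, 10 GPi, 10 thalamic,
    10 TRN).  ``coupling_*`` exponents convert signal differences from the
    untreated reference heterozygote into multiplicative pathway gains.
    """

    n_ctx_e: int = 40
    n_ctx_i: int = 10
    n_d1: int = 20
    n_d2: int = 20
    n_gpi: int = 10
    n_thal: int = 10
    n_trn: int = 10
    dt_ms: float = 1.0
    duration_s: float = 4.0
    warmup_s: float = 0.5
    ctx_drive: float = 0.75
    noise_sd: float = 2.8  # fluctuation-driven regime; scaled by pathology noise gain
    coupling_d1: float = 3.0  # direct-pathway gain per unit striatal D1-signal change
    coupling_d2: float = 4.0  # indirect-pathway disinhibition per unit D2-signal drop
    coupling_d1_cortical: float = 5.0  # cortical excitability per unit cortical D1 change
    coupling_5ht2a: float = 1.5  # cortical excitability per unit 5HT2A-signal change
    coupling_5ht1a: float = 0.8  # cortical stabilisation by 5HT1A agonism
    weights: Mapping[str, float] = field(
        default_factory=lambda: {
            "ctx_e->ctx_e": 0.3,
            "ctx_e->ctx_i": 0.8,
            "ctx_i->ctx_e": -0.8,
            "ctx_e->d1": 1.8,
            "ctx_e->d2": 1.8,
            "d1->gpi": -1.2,
            "d2->gpi": 1.0,
            "gpi->thal": -1.1,
            "thal->trn": 1.4,
            "trn->thal": -0.5,
            "thal->ctx_e": 0.3,
            "ctx_e->thal": 0.4,
        }
    )
    biases: Mapping[str, float] = field(
        default_factory=lambda: {
            "ctx_i": 0.3,
            "msn": 0.1,
            "gpi": 0.95,
            "thal": 0.95,
            "trn": 0.45,
        }
    )
    reference_signals: Mapping[str, float] | None = None  # None -> computed default


@dataclass(frozen=True)
class SpikeRaster:
    """Spike raster of one population: (unit index, spike time s) pairs."""

    n_units: int
    spikes: tuple[tuple[int, float], ...]
    duration: float

    def __post_init__(self) -> None:
        for unit, t in self.spikes:
            if not 0 <= unit < self.n_units:
                raise ValueError(f"unit index {unit} outside [0, {self.n_units})")
            if not 0.0 <= t <= self.duration:
                raise ValueError(f"spike time {t} outside [0, {self.duration}]")

    @classmethod
    def from_bool_matrix(cls, mat: np.ndarray, dt_ms: float) -> "SpikeRaster":
        steps, n = mat.shape
        t_idx, u_idx = np.nonzero(mat)
        pairs = tuple(
            (int(u), float(t) * dt_ms / 1000.0) for u, t in zip(u_idx, t_idx)
        )
        pairs = tuple(sorted(pairs))
        return cls(n_units=n, spikes=pairs, duration=steps * dt_ms / 1000.0)

    def binned(self, bin_ms: float) -> np.ndarray:
        """Binary (unit x bin) matrix: 1 where the unit spiked in the bin."""
        n_bins = int(math.floor(self.duration * 1000.0 / bin_ms))
        out = np.zeros((self.n_units, n_bins), dtype=bool)
        for unit, t in self.spikes:
            b = int(t * 1000.0 / bin_ms)
            if b < n_bins:
                out[unit, b] = True
        return out

    def mean_rate(self) -> float:
        """Population mean firing rate in Hz."""
        return len(self.spikes) / (self.n_units * self.duration)


def _gain(coupling: float, signal: float, reference: float) -> float:
    return math.exp(coupling * (signal - reference))


def run_cstc_loop(
    config: LoopConfig,
    drug_signals: Mapping[str, float],
    effects: GenotypeEffects,
    pathology: PathologyParams,
    seed: int,
) -> SpikeRaster:
    """Simulate the loop and return the TRN spike raster.

    ``drug_signals`` must contain striatal "D1" and "D2" and cortical "5HT2A"
    and "5HT1A" signals computed by the pharmacology layer at the
    genotype-adjusted basal tone (D2 already scaled by the DRD2 expression
    scale).  Deterministic given (config, seed).
    """
    ref = config.reference_signals
    if ref is None:
        cortical_ref = reference_signals(pathology, "cortical")
        ref = {
            **reference_signals(pathology, "striatal"),
            "5HT2A": cortical_ref["5HT2A"],
            "5HT1A": cortical_ref["5HT1A"],
            "D1_cortical": cortical_ref["D1"],
        }
    g_d1 = _gain(config.coupling_d1, drug_signals["D1"], ref["D1"])
    g_d2 = _gain(-config.coupling_d2, drug_signals["D2"], ref["D2"])
    g_ctx = _gain(config.coupling_5ht2a, drug_signals["5HT2A"], ref["5HT2A"]) * _gain(
        -config.coupling_5ht1a, drug_signals["5HT1A"], ref["5HT1A"]
    )
    if "D1_cortical" in drug_signals and "D1_cortical" in ref:
        g_ctx *= _gain(
            config.coupling_d1_cortical, drug_signals["D1_cortical"], ref["D1_cortical"]
        )
    w = config.weights
    b = config.biases
    glu = 1.0 - pathology.glu_deficit
    gaba = 1.0 - pathology.gaba_deficit
    nz = config.noise_sd
    ng = pathology.noise_gain

    pops = [
        PopulationSpec("ctx_e", config.n_ctx_e, tau_m=15.0, bias=config.ctx_drive * glu * g_ctx,
                       noise_sd=nz * ng),
        PopulationSpec("ctx_i", config.n_ctx_i, tau_m=10.0, bias=b["ctx_i"], noise_sd=nz * ng),
        PopulationSpec("d1", config.n_d1, tau_m=10.0, bias=b["msn"], noise_sd=nz),
        PopulationSpec("d2", config.n_d2, tau_m=10.0, bias=b["msn"], noise_sd=nz),
        PopulationSpec("gpi", config.n_gpi, tau_m=8.0, bias=b["gpi"], noise_sd=nz),
        PopulationSpec("thal", config.n_thal, tau_m=10.0, bias=b["thal"], noise_sd=nz * ng),
        PopulationSpec("trn", config.n_trn, tau_m=10.0, bias=b["trn"], noise_sd=nz),
    ]
    conns = [
        Connection("ctx_e", "ctx_e", w["ctx_e->ctx_e"] * glu, 5.0),
        Connection("ctx_e", "ctx_i", w["ctx_e->ctx_i"], 5.0),
        Connection("ctx_i", "ctx_e", w["ctx_i->ctx_e"] * gaba, 8.0),
        Connection("ctx_e", "d1", w["ctx_e->d1"] * glu * g_d1, 5.0),
        Connection("ctx_e", "d2", w["ctx_e->d2"] * glu * g_d2, 5.0),
        Connection("d1", "gpi", w["d1->gpi"], 8.0),
        Connection("d2", "gpi", w["d2->gpi"], 12.0),
        Connection("gpi", "thal", w["gpi->thal"], 8.0),
        Connection("thal", "trn", w["thal->trn"], 5.0),
        Connection("trn", "thal", w["trn->thal"], 10.0),
        Connection("thal", "ctx_e", w["thal->ctx_e"], 5.0),
        Connection("ctx_e", "thal", w["ctx_e->thal"] * glu, 5.0),
    ]
    net = LifNetwork(pops, conns, dt_ms=config.dt_ms)
    res: SimResult = net.run(
        config.duration_s, seed=seed, record=("trn",), warmup_s=config.warmup_s
    )
    raster = SpikeRaster.from_bool_matrix(res.spikes["trn"], config.dt_ms)
    if not np.isfinite([t for _, t in raster.spikes] or [0.0]).all():
        raise FloatingPointError("non-finite spike times: circuit unstable")
    return raster


def shannon_entropy(raster: SpikeRaster, bin_ms: float = 10.0, word_length: int = 3) -> float:
    """Plug-in Shannon entropy (bits per word) of binary TRN spike words.

    Each unit's spike train is binarised in ``bin_ms`` bins; overlapping words
    of ``word_length`` consecutive bins are pooled across units and the
    entropy of the empirical word distribution, ``-sum p log2 p``, is
    returned.  Bounded by log2 of the number of distinct observed words.
    """
    if raster.duration <= 0:
        raise ValueError("raster duration must be > 0")
    if bin_ms <= 0 or word_length < 1:
        raise ValueError("bin_ms must be > 0 and word_length >= 1")
    min_duration = 100.0 * bin_ms * word_length / 1000.0
    if raster.duration < min_duration:
        raise ValueError(
            f"duration {raster.duration} s too short for a stable plug-in estimate "
            f"(need >= {min_duration} s)"
        )
    bins = raster.binned(bin_ms)
    n_units, n_bins = bins.shape
    n_words = n_bins - word_length + 1
    if n_words < 1:
        raise ValueError("raster shorter than one word")
    powers = 1 << np.arange(word_length)
    codes = np.zeros((n_units, n_words), dtype=np.int64)
    for k in range(word_length):
        codes += bins[:, k : k + n_words].astype(np.int64) * powers[k]
    _, counts = np.unique(codes.ravel(), return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


@dataclass(frozen=True)
class PanssCalibration:
    """Anchors mapping relative TRN entropy change onto change in PANSS Total.

    Piecewise-linear through the anchors (affine for the two-anchor default),
    linearly extrapolated beyond them; anchors are reproduced exactly.
    """

    # Placebo anchored at -8 points; the second anchor is the mean relative
    # entropy change of the reference heterozygote on 10 mg haloperidol in
    # this circuit realisation, pinned to a -17 point response (mid clinical
    # range).  Surrogate calibration, config-exposed.
    anchors: tuple[tuple[float, float], ...] = ((0.0, -8.0), (-0.036, -17.0))

    def __post_init__(self) -> None:
        if len(self.anchors) < 2:
            raise ValueError("need at least 2 calibration anchors")
        xs = [x for x, _ in self.anchors]
        if len(set(xs)) != len(xs):
            raise ValueError("degenerate calibration: duplicate anchor abscissae")

    def __call__(self, rel_change: float) -> float:
        pts = sorted(self.anchors)
        xs = np.array([x for x, _ in pts])
        ys = np.array([y for _, y in pts])
        if rel_change <= xs[0]:
            slope = (ys[1] - ys[0]) / (xs[1] - xs[0])
            return float(ys[0] + slope * (rel_change - xs[0]))
        if rel_change >= xs[-1]:
            slope = (ys[-1] - ys[-2]) / (xs[-1] - xs[-2])
            return float(ys[-1] + slope * (rel_change - xs[-1]))
        return float(np.interp(rel_change, xs, ys))


def entropy_to_delta_panss(
    entropy_treated: float,
    entropy_untreated: float,
    cal: PanssCalibration = PanssCalibration(),
) -> float:
    """Change in PANSS Total (points) from the relative entropy change.

    ``rel = (H_treated - H_untreated) / H_untreated`` is passed through the
    affine calibration; a zero change returns the placebo anchor.  The
    untreated reference is the pathological reference-heterozygote run, so
    genotype effects shift the placebo response through their effect on the
    untreated entropy.
    """
    if entropy_untreated <= 0:
        raise ValueError("untreated entropy must be > 0")
    rel = (entropy_treated - entropy_untreated) / entropy_untreated
    return cal(rel)


def dose_response_slope(
    doses: Sequence[float], outcomes: Sequence[float]
) -> float:
    """OLS slope of outcome against dose, per 100% of the standard dose.

    ``doses`` are fractions of the standard dose (the fitting range in the
    study design spans 20-140%), so the least-squares slope in those units is
    already points per 100% dose change.
    """
    doses = np.asarray(doses, dtype=float)
    outcomes = np.asarray(outcomes, dtype=float)
    if doses.size < 3:
        raise ValueError("need >= 3 dose points for a slope fit")
    if doses.size != outcomes.size:
        raise ValueError("doses and outcomes must have equal length")
    slope, _ = np.polyfit(doses, outcomes, 1)
    return float(slope)
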