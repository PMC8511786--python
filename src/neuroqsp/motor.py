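"""Motor-territory basal-ganglia loop, STN field-potential proxy and EPS readout.

The motor surrogate extends the cortical/striatal stage of the associative
loop with an external-pallidum (GPe) and subthalamic (STN) pair.  The STN
receives two currents: a fast hyperdirect cortical input (3 ms kinetics, the
gamma-band carrier) and a slow indirect-pathway input (12 ms kinetics, the
beta-band carrier) whose source is the D2-expressing striatal population with
the disynaptic pallidal relay collapsed into an effective disinhibitory
kernel — the same collapse the associative loop applies between striatum and
pallidum.  D2 antagonism (or low striatal D2 expression) disinhibits the
D2-MSNs, strengthens the slow current, and shifts power of the STN
field-potential proxy from gamma toward beta — the electrophysiological
signature of rigidity and bradykinesia.  An explicit GPe<->STN pair with a
fixed modest gain supplies pallido-subthalamic temporal structure.

The field-potential proxy is the summed rectified synaptic current into the
STN units.  The clinical endpoint maps the Welch beta/gamma band-power ratio
through a logistic curve onto the fraction of patients requiring
anticholinergic medication (EPS probability).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import signal as sps

from .genotypes import GenotypeEffects
from .network import Connection, LifNetwork, PopulationSpec
from .signals import PathologyParams, reference_signals

__all__ = [
    "MotorLoopConfig",
    "LfpTrace",
    "EpsCalibration",
    "run_motor_loop",
    "band_power_ratio",
    "ratio_to_eps_probability",
]

BETA_BAND = (13.0, 30.0)
GAMMA_BAND = (30.0, 80.0)


@dataclass(frozen=True)
class LfpTrace:
    """Local-field-potential proxy: sample series plus its sampling rate."""

    samples: np.ndarray
    sampling_rate: float  # Hz

    def __post_init__(self) -> None:
        if self.sampling_rate < 200.0:
            raise ValueError("sampling_rate must be >= 200 Hz to resolve gamma")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("LFP samples must be finite")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sampling_rate


@dataclass(frozen=True)
class MotorLoopConfig:
    """Motor loop structure; shares the cortical/striatal stage with the
    associative loop and adds the GPe-STN resonator."""

    n_ctx_e: int = 40
    n_ctx_i: int = 10
    n_d1: int = 20
    n_d2: int = 20
    n_gpe: int = 10
    n_stn: int = 10
    n_gpi: int = 10
    dt_ms: float = 1.0
    duration_s: float = 5.0
    warmup_s: float = 1.0
    ctx_drive: float = 0.75
    noise_sd: float = 2.8
    coupling_d1: float = 3.0
    # kept below the associative-loop value so the D2-MSNs stay in the
    # irregular (fluctuation-driven) regime across the whole drug range
    coupling_d2: float = 2.5
    coupling_5ht2a: float = 1.5
    weights: Mapping[str, float] = field(
        default_factory=lambda: {
            "ctx_e->ctx_i": 0.8,
            "ctx_i->ctx_e": -0.8,
            "ctx_e->d1": 1.8,
            "ctx_e->d2": 1.8,
            "ctx_e->stn": 0.7,  # hyperdirect, fast (gamma carrier)
            "d2->stn": 1.2,  # collapsed pallidal disinhibition, slow (beta carrier)
            "d2->gpe": -0.5,
            "gpe->stn": -0.4,
            "stn->gpe": 0.4,
            "stn->gpi": 0.6,
            "d1->gpi": -1.2,
        }
    )
    biases: Mapping[str, float] = field(
        default_factory=lambda: {
            "ctx_i": 0.3,
            "msn": 0.1,
            "gpe": 1.0,
            "stn": 0.7,
            "gpi": 0.95,
        }
    )
    reference_signals: Mapping[str, float] | None = None


def run_motor_loop(
    config: MotorLoopConfig,
    drug_signals: Mapping[str, float],
    effects: GenotypeEffects,
    pathology: PathologyParams,
    seed: int,
) -> LfpTrace:
    """Simulate the motor loop and return the STN field-potential proxy.

    Deterministic given (config, seed); with zero noise and zero drive the
    trace has zero variance.
    """
    ref = config.reference_signals
    if ref is None:
        cortical_ref = reference_signals(pathology, "cortical")
        ref = {
            **reference_signals(pathology, "striatal"),
            "5HT2A": cortical_ref["5HT2A"],
            "5HT1A": cortical_ref["5HT1A"],
        }
    s_d2 = drug_signals["D2"]
    g_d1 = math.exp(config.coupling_d1 * (drug_signals["D1"] - ref["D1"]))
    g_d2 = math.exp(-config.coupling_d2 * (s_d2 - ref["D2"]))
    g_ctx = math.exp(config.coupling_5ht2a * (drug_signals["5HT2A"] - ref["5HT2A"]))
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
        PopulationSpec("gpe", config.n_gpe, tau_m=6.0, bias=b["gpe"], noise_sd=nz),
        PopulationSpec("stn", config.n_stn, tau_m=6.0, bias=b["stn"], noise_sd=nz),
        PopulationSpec("gpi", config.n_gpi, tau_m=8.0, bias=b["gpi"], noise_sd=nz),
    ]
    conns = [
        Connection("ctx_e", "ctx_i", w["ctx_e->ctx_i"], 5.0),
        Connection("ctx_i", "ctx_e", w["ctx_i->ctx_e"] * gaba, 8.0),
        Connection("ctx_e", "d1", w["ctx_e->d1"] * glu * g_d1, 5.0),
        Connection("ctx_e", "d2", w["ctx_e->d2"] * glu * g_d2, 5.0),
        Connection("ctx_e", "stn", w["ctx_e->stn"] * glu, 3.0),
        Connection("d2", "stn", w["d2->stn"], 12.0),
        Connection("d2", "gpe", w["d2->gpe"], 10.0),
        Connection("gpe", "stn", w["gpe->stn"], 8.0),
        Connection("stn", "gpe", w["stn->gpe"], 4.0),
        Connection("stn", "gpi", w["stn->gpi"], 5.0),
        Connection("d1", "gpi", w["d1->gpi"], 8.0),
    ]
    net = LifNetwork(pops, conns, dt_ms=config.dt_ms)
    res = net.run(
        config.duration_s,
        seed=seed,
        record=(),
        lfp_into="stn",
        warmup_s=config.warmup_s,
    )
    return LfpTrace(samples=res.lfp, sampling_rate=1000.0 / config.dt_ms)


def band_power_ratio(
    trace: LfpTrace,
    beta_band: tuple[float, float] = BETA_BAND,
    gamma_band: tuple[float, float] = GAMMA_BAND,
    window_s: float = 1.0,
    ratio_cap: float = 1e6,
) -> float:
    """Welch beta/gamma band-power ratio of an LFP trace.

    Welch estimation with Hann windows of ``window_s`` seconds and 50%
    overlap; band powers are PSD integrals over the band.  A zero-power gamma
    band returns ``ratio_cap`` with a warning instead of dividing by zero.
    """
    fs = trace.sampling_rate
    if fs <= 2.0 * gamma_band[1]:
        raise ValueError(
            f"sampling rate {fs} Hz violates Nyquist for gamma upper edge {gamma_band[1]} Hz"
        )
    if trace.duration < 4.0:
        raise ValueError("trace must be at least 4 s long")
    nperseg = int(round(window_s * fs))
    freqs, psd = sps.welch(
        trace.samples, fs=fs, window="hann", nperseg=nperseg, noverlap=nperseg // 2
    )
    beta = _band_power(freqs, psd, beta_band)
    gamma = _band_power(freqs, psd, gamma_band)
    if gamma <= 0.0:
        warnings.warn("zero gamma power; returning capped beta/gamma ratio")
        return ratio_cap
    return min(beta / gamma, ratio_cap)


def _band_power(freqs: np.ndarray, psd: np.ndarray, band: tuple[float, float]) -> float:
    lo, hi = band
    mask = (freqs >= lo) & (freqs <= hi)
    if mask.sum() < 2:
        raise ValueError(f"band {band} under-resolved by the spectral estimate")
    return float(np.trapezoid(psd[mask], freqs[mask]))


@dataclass(frozen=True)
class EpsCalibration:
    """Logistic map from beta/gamma ratio to EPS probability.

    Defaults place the untreated reference genotype inside the 16-32% span
    reported for placebo subjects; both parameters are surrogate calibration,
    config-exposed.
    """

    midpoint: float = 1.74
    slope: float = 2.0

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("slope must be > 0")


def ratio_to_eps_probability(ratio: float, cal: EpsCalibration = EpsCalibration()) -> float:
    """Fraction of patients needing anticholinergics, strictly increasing in ratio."""
    if ratio <= 0:
        raise ValueError("beta/gamma ratio must be > 0")
    return 1.0 / (1.0 + math.exp(-cal.slope * (ratio - cal.midpoint)))
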