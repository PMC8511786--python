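"""Three-locus pharmacogenetics: COMT Val158Met, 5-HTTLPR rs25531, DRD2 Taq1A.

Each locus has three levels and a single well-documented physiological
consequence used by the circuit models:

* COMT Met slows cortical dopamine clearance — synaptic half-life 100 ms
  (VV), 130 ms (MV), 160 ms (MM).  Striatal clearance is COMT-independent.
* 5-HTTLPR L raises transporter expression and speeds serotonin clearance —
  half-life 55 ms (LL), 75 ms (Ls), 100 ms (ss), in all compartments.
* DRD2 Taq1A scales striatal D2 receptor expression — 0.7 (A1A1), 1.0
  (A1A2), 1.3 (A2A2); cortical D2 availability is assumed unaffected.

Population structure over the 27 combinations follows Hardy-Weinberg
equilibrium with independent loci.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

COMT_LEVELS = ("MM", "MV", "VV")
HTTLPR_LEVELS = ("LL", "Ls", "ss")
DRD2_LEVELS = ("A1A1", "A1A2", "A2A2")
LOCI = ("comt", "httlpr", "drd2")
_LEVELS = {"comt": COMT_LEVELS, "httlpr": HTTLPR_LEVELS, "drd2": DRD2_LEVELS}

#: Cortical dopamine synaptic half-life (ms) per COMT genotype.
TAU_DA_CORTICAL_MS = {"VV": 100.0, "MV": 130.0, "MM": 160.0}
#: Serotonin synaptic half-life (ms) per 5-HTTLPR genotype.
TAU_5HT_MS = {"LL": 55.0, "Ls": 75.0, "ss": 100.0}
#: Striatal D2 receptor expression scale per DRD2 Taq1A genotype.
D2R_SCALE = {"A1A1": 0.7, "A1A2": 1.0, "A2A2": 1.3}

#: Reference (fully heterozygous) genotype used for calibration baselines.
REFERENCE_GENOTYPE_STRING = "MV/Ls/A1A2"


@dataclass(frozen=True, order=True)
class GenotypeState:
    """One of the 27 three-locus genotype combinations (``"C/S/D"`` form)."""

    comt: str
    httlpr: str
    drd2: str

    def __post_init__(self) -> None:
        for locus, value in zip(LOCI, (self.comt, self.httlpr, self.drd2)):
            if value not in _LEVELS[locus]:
                raise ValueError(
                    f"invalid {locus} genotype {value!r}; expected one of {_LEVELS[locus]}"
                )

    def __str__(self) -> str:
        return f"{self.comt}/{self.httlpr}/{self.drd2}"

    @classmethod
    def parse(cls, text: str) -> "GenotypeState":
        parts = text.strip().split("/")
        if len(parts) != 3:
            raise ValueError(f"genotype string must have 3 '/'-separated loci, got {text!r}")
        return cls(*parts)


@dataclass(frozen=True)
class GenotypeEffects:
    """Synaptic parameters implied by a genotype."""

    tau_da_cortical: float  # ms
    tau_5ht: float  # ms
    d2r_scale: float  # dimensionless


def genotype_effects(g: GenotypeState | str) -> GenotypeEffects:
    """Map a genotype to its synaptic parameter triple."""
    if isinstance(g, str):
        g = GenotypeState.parse(g)
    return GenotypeEffects(
        tau_da_cortical=TAU_DA_CORTICAL_MS[g.comt],
        tau_5ht=TAU_5HT_MS[g.httlpr],
        d2r_scale=D2R_SCALE[g.drd2],
    )


REFERENCE_GENOTYPE = GenotypeState.parse(REFERENCE_GENOTYPE_STRING)


def enumerate_genotypes() -> tuple[GenotypeState, ...]:
    """All 27 genotype combinations in canonical (COMT, 5-HTTLPR, DRD2) order."""
    return tuple(
        GenotypeState(c, s, d)
        for c, s, d in itertools.product(COMT_LEVELS, HTTLPR_LEVELS, DRD2_LEVELS)
    )


def _locus_probability(level: str, levels: Sequence[str], p: float) -> float:
    """Hardy-Weinberg probability of ``level``; ``p`` is the first-allele frequency."""
    if not 0.0 < p < 1.0:
        raise ValueError(f"allele frequency must be in (0, 1), got {p}")
    q = 1.0 - p
    return {levels[0]: p * p, levels[1]: 2.0 * p * q, levels[2]: q * q}[level]


def hardy_weinberg_weight(
    g: GenotypeState | str,
    allele_freq: float | Mapping[str, float] = 0.5,
) -> float:
    """Hardy-Weinberg population probability of a 3-locus genotype.

    ``allele_freq`` is the frequency of the first-listed allele per locus
    (M for COMT, L for 5-HTTLPR, A1 for DRD2), either one value for all loci
    or a mapping keyed by locus name.  Loci are independent.
    """
    if isinstance(g, str):
        g = GenotypeState.parse(g)
    freqs = _normalize_freqs(allele_freq)
    w = 1.0
    for locus, value in zip(LOCI, (g.comt, g.httlpr, g.drd2)):
        w *= _locus_probability(value, _LEVELS[locus], freqs[locus])
    return w


def _normalize_freqs(allele_freq: float | Mapping[str, float]) -> dict[str, float]:
    if isinstance(allele_freq, Mapping):
        return {locus: float(allele_freq.get(locus, 0.5)) for locus in LOCI}
    return {locus: float(allele_freq) for locus in LOCI}


def population_weights(
    allele_freq: float | Mapping[str, float] = 0.5,
) -> dict[GenotypeState, float]:
    """Hardy-Weinberg weights over all 27 genotypes (sum to 1)."""
    return {g: hardy_weinberg_weight(g, allele_freq) for g in enumerate_genotypes()}


def matches_pattern(g: GenotypeState, pattern: str) -> bool:
    """True if genotype matches a ``"C/S/D"`` pattern with ``*`` wildcards."""
    parts = pattern.strip().split("/")
    if len(parts) != 3:
        raise ValueError(f"pattern must have 3 '/'-separated loci, got {pattern!r}")
    for part, value, locus in zip(parts, (g.comt, g.httlpr, g.drd2), LOCI):
        if part == "*":
            continue
        if part not in _LEVELS[locus]:
            raise ValueError(f"invalid {locus} level {part!r} in pattern {pattern!r}")
        if part != value:
            return False
    return True


def marginalize(
    outcomes: Mapping[GenotypeState, float],
    fixed: str = "*/*/*",
    allele_freq: float | Mapping[str, float] = 0.5,
) -> float:
    """Hardy-Weinberg-weighted mean of ``outcomes`` over genotypes matching ``fixed``.

    Weights are renormalized to sum to 1 over the matching subset.  Raises if
    any matching genotype is missing from the outcome table.
    """
    matching = [g for g in enumerate_genotypes() if matches_pattern(g, fixed)]
    missing = [str(g) for g in matching if g not in outcomes]
    if missing:
        raise KeyError(f"incomplete outcome table; missing genotypes: {', '.join(missing)}")
    weights = [hardy_weinberg_weight(g, allele_freq) for g in matching]
    total = sum(weights)
    return sum(w * outcomes[g] for g, w in zip(matching, weights)) / total


def weighted_population_mean(
    outcomes: Mapping[GenotypeState, float],
    allele_freq: float | Mapping[str, float] = 0.5,
) -> float:
    """Population mean over all 27 genotypes (full-wildcard marginalization)."""
    return marginalize(outcomes, "*/*/*", allele_freq)
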