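"""Synthetic inputs: virtual drug profiles, noisy PET anchors, genotype cohorts.

Everything the pipeline consumes can be generated here without downloads.
Virtual drugs follow the strong-D2-antagonist / weak-D2-antagonist /
D2-partial-agonist taxonomy, with log-uniform affinities inside archetype
ranges chosen so that strong-D2 drugs reach >= 70% D2 occupancy at their
standard-dose-equivalent concentration while weak-D2 drugs stay <= 50%.
Occupancy anchors are produced from a profile's own binding closed form plus
truncated Gaussian noise (a stand-in for published PET occupancy-versus-dose
data), and cohorts are Hardy-Weinberg draws over the 27 genotypes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genotypes import COMT_LEVELS, DRD2_LEVELS, HTTLPR_LEVELS, GenotypeState
from .pharmacology import (
    DrugProfile,
    SynapseParams,
    occupancy_to_concentration,
    receptor_occupancy,
    steady_state_level,
)
from .signals import DEFAULT_LIGAND_KI


@dataclass(frozen=True)
class DrugArchetype:
    """Affinity/efficacy ranges for one class of virtual antipsychotic."""

    label: str
    d2_ki_range: tuple[float, float]  # nM, log-uniform
    d2_efficacy_range: tuple[float, float]
    other_ki_range: tuple[float, float] = (5.0, 5000.0)
    standard_dose: float = 10.0  # mg
    standard_occupancy: float = 0.8  # D2 occupancy at the standard dose

    def __post_init__(self) -> None:
        for lo, hi in (self.d2_ki_range, self.other_ki_range):
            if not 0 < lo < hi:
                raise ValueError("Ki ranges must be non-degenerate and positive")


ARCHETYPES: dict[str, DrugArchetype] = {
    "strong_d2_antagonist": DrugArchetype(
        "strong_d2_antagonist", d2_ki_range=(0.5, 5.0), d2_efficacy_range=(0.0, 0.0),
        standard_occupancy=0.8,
    ),
    "weak_d2_antagonist": DrugArchetype(
        "weak_d2_antagonist", d2_ki_range=(50.0, 500.0), d2_efficacy_range=(0.0, 0.0),
        standard_dose=200.0, standard_occupancy=0.4,
    ),
    "d2_partial_agonist": DrugArchetype(
        "d2_partial_agonist", d2_ki_range=(0.3, 3.0), d2_efficacy_range=(0.2, 0.4),
        standard_dose=20.0, standard_occupancy=0.85,
    ),
}

_OTHER_RECEPTORS = ("D1", "D4", "5HT1A", "5HT2A", "5HT3", "5HT6", "M1", "alpha1", "alpha2", "H1")


def _log_uniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(math.exp(rng.uniform(math.log(lo), math.log(hi))))


def generate_drug_profile(
    archetype: str | DrugArchetype,
    seed: int,
    synapse: SynapseParams | None = None,
) -> DrugProfile:
    """Deterministic virtual drug for an archetype.

    Anchors are noise-free by construction: the concentration at the standard
    dose is the one achieving the archetype's target D2 occupancy against the
    given striatal dopamine competition (default: pathological basal tone),
    and concentration scales proportionally with dose.
    """
    if isinstance(archetype, str):
        try:
            archetype = ARCHETYPES[archetype]
        except KeyError:
            raise ValueError(f"unknown archetype {archetype!r}") from None
    if synapse is None:
        from .signals import DEFAULT_SYNAPSES, PathologyParams

        synapse = DEFAULT_SYNAPSES.striatal_dopamine(PathologyParams())
    rng = np.random.default_rng(seed)
    d2_ki = _log_uniform(rng, *archetype.d2_ki_range)
    lo, hi = archetype.d2_efficacy_range
    d2_alpha = float(rng.uniform(lo, hi)) if hi > lo else float(lo)
    affinities = {"D2": d2_ki}
    for receptor in _OTHER_RECEPTORS:
        affinities[receptor] = _log_uniform(rng, *archetype.other_ki_range)
    efficacies = {"D2": d2_alpha} if d2_alpha > 0 else {}

    ligand = steady_state_level(synapse)
    anchors = _noise_free_anchors(
        archetype.standard_dose,
        archetype.standard_occupancy,
        d2_ki,
        ligand,
        DEFAULT_LIGAND_KI["D2"],
    )
    return DrugProfile(
        name=f"{archetype.label}_{seed}",
        standard_dose=archetype.standard_dose,
        affinities=affinities,
        efficacies=efficacies,
        occupancy_anchors=anchors,
    )


def _noise_free_anchors(
    standard_dose: float,
    standard_occ: float,
    ki: float,
    ligand: float,
    ligand_ki: float,
    fractions: Sequence[float] = (0.5, 1.0, 1.4),
) -> list[tuple[float, float]]:
    c_std = occupancy_to_concentration(standard_occ, ki, ligand, ligand_ki)
    anchors = []
    rl = ligand / ligand_ki
    for f in fractions:
        conc = c_std * f
        rd = conc / ki
        anchors.append((standard_dose * f, rd / (1.0 + rl + rd)))
    return anchors


def generate_occupancy_anchors(
    profile: DrugProfile,
    synapse: SynapseParams,
    noise_sd: float,
    seed: int,
    dose_fractions: Sequence[float] = (0.25, 0.5, 1.0, 1.5, 2.0),
) -> list[tuple[float, float]]:
    """Noisy occupancy-versus-dose anchors from the profile's own binding.

    Concentration is proportional to dose through the profile's existing
    standard-dose anchor; Gaussian noise (sd ``noise_sd``, truncated at
    1.5 sd) is added to each occupancy, clipped into (0, 1) and monotonized
    by a running maximum so the anchor invariants hold for any draw.  The
    tight truncation bounds the concentration error of the inverse problem:
    near-saturating anchors amplify occupancy noise by 1/(occ x (1 - occ)).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    ligand = steady_state_level(synapse)
    ki = profile.ki("D2")
    std_anchor = min(
        profile.occupancy_anchors, key=lambda a: abs(a[0] - profile.standard_dose)
    )
    c_std = occupancy_to_concentration(std_anchor[1], ki, ligand, DEFAULT_LIGAND_KI["D2"])
    c_std *= profile.standard_dose / std_anchor[0]
    anchors = []
    rl = ligand / DEFAULT_LIGAND_KI["D2"]
    for f in dose_fractions:
        rd = c_std * f / ki
        occ = rd / (1.0 + rl + rd)
        if noise_sd > 0:
            occ += float(
                np.clip(rng.normal(0.0, noise_sd), -1.5 * noise_sd, 1.5 * noise_sd)
            )
        anchors.append((profile.standard_dose * f, float(np.clip(occ, 1e-3, 1 - 1e-3))))
    occs = np.maximum.accumulate([o for _, o in anchors])
    return [(d, float(o)) for (d, _), o in zip(anchors, occs)]


def sample_cohort(
    n: int,
    allele_freqs: Mapping[str, float] | float = 0.5,
    seed: int = 0,
) -> list[GenotypeState]:
    """Hardy-Weinberg cohort of ``n`` independent 3-locus genotypes."""
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    if isinstance(allele_freqs, Mapping):
        freqs = {k: float(allele_freqs.get(k, 0.5)) for k in ("comt", "httlpr", "drd2")}
    else:
        freqs = {k: float(allele_freqs) for k in ("comt", "httlpr", "drd2")}
    rng = np.random.default_rng(seed)
    levels = {"comt": COMT_LEVELS, "httlpr": HTTLPR_LEVELS, "drd2": DRD2_LEVELS}
    draws = {}
    for locus, lvls in levels.items():
        # number of copies of the second-listed allele: 0 -> first homozygote
        k = rng.binomial(2, 1.0 - freqs[locus], size=n)
        draws[locus] = [lvls[int(x)] for x in k]
    return [
        GenotypeState(c, s, d)
        for c, s, d in zip(draws["comt"], draws["httlpr"], draws["drd2"])
    ]


def perturb_outcomes(table: pd.DataFrame, noise_sd: float, seed: int) -> pd.DataFrame:
    """Element-wise Gaussian perturbation of the outcome values (schema kept)."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    out = table.copy()
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        out["value"] = out["value"] + rng.normal(0.0, noise_sd, size=len(out))
    return out
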