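"""Factorial study orchestration and genotype-specific drug ranking.

The full design crosses the 7 antipsychotics (at their standard clinical
doses, optionally a 20-140% dose grid) with the 27 three-locus genotypes and
the three clinical endpoints, plus an untreated (placebo) arm per genotype.
Outcomes are collected in a tidy table; single-gene aggregates marginalise the
two other loci with Hardy-Weinberg weights; and the personalization table
centres every endpoint on its genotype-frequency-weighted cross-drug average,
rank-orders the drugs (1-7, lower = better, average ranks on ties), and sums
ranks across the three endpoints.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from . import cognition as cog
from . import efficacy as eff
from . import motor as mot
from .datasets import DRUG_ORDER, load_drug_profiles
from .genotypes import (
    GenotypeState,
    REFERENCE_GENOTYPE,
    enumerate_genotypes,
    genotype_effects,
    hardy_weinberg_weight,
    marginalize,
)
from .pharmacology import DrugProfile
from .signals import PathologyParams, receptor_signals

ENDPOINTS = ("panss", "eps", "cognition")
PLACEBO = "placebo"

#: Endpoint orientation: +1 if lower values are clinically better.
_LOWER_IS_BETTER = {"panss": 1.0, "eps": 1.0, "cognition": -1.0}


@dataclass(frozen=True)
class StudyDesign:
    """What to simulate: drugs, dose grid, genotypes, endpoints, replicates."""

    drugs: tuple[str, ...] = DRUG_ORDER
    dose_fractions: tuple[float, ...] = (1.0,)
    genotypes: tuple[GenotypeState, ...] = field(default_factory=enumerate_genotypes)
    endpoints: tuple[str, ...] = ENDPOINTS
    n_seeds: int = 1

    def __post_init__(self) -> None:
        for f in self.dose_fractions:
            if not 0.2 <= f <= 1.4:
                raise ValueError("dose fractions must lie in [0.2, 1.4]")
        if self.n_seeds < 1:
            raise ValueError("need at least one replicate seed")
        unknown = set(self.endpoints) - set(ENDPOINTS)
        if unknown:
            raise ValueError(f"unknown endpoints: {sorted(unknown)}")


@dataclass(frozen=True)
class StudyConfigs:
    """Bundle of module configurations used by every cell of the study."""

    pathology: PathologyParams = PathologyParams()
    loop: eff.LoopConfig = eff.LoopConfig()
    motor: mot.MotorLoopConfig = mot.MotorLoopConfig()
    cortical: cog.CorticalNetworkConfig = cog.CorticalNetworkConfig()
    stimulus: cog.StimulusProtocol = cog.StimulusProtocol()
    panss_cal: eff.PanssCalibration = eff.PanssCalibration()
    eps_cal: mot.EpsCalibration = mot.EpsCalibration()
    accuracy_cal: cog.AccuracyCalibration = cog.AccuracyCalibration(as_patient=True)
    wm_threshold: float = 10.0
    allele_freq: float = 0.5


def _cell_seed(master_seed: int, *components: int) -> int:
    """Stable per-cell seed below 2**31 derived from the master seed."""
    ss = np.random.SeedSequence([int(master_seed), *[int(c) for c in components]])
    return int(ss.generate_state(1)[0] % (2**31))


_COMT_IDX = {"MM": 0, "MV": 1, "VV": 2}
_HTT_IDX = {"LL": 0, "Ls": 1, "ss": 2}
_DRD2_IDX = {"A1A1": 0, "A1A2": 1, "A2A2": 2}


def _genotype_seed_components(g: GenotypeState, endpoint: str) -> tuple[int, int, int]:
    # Cognition deliberately ignores the DRD2 locus so that its outputs are
    # bit-identical across DRD2 levels at a fixed master seed.
    drd2 = 0 if endpoint == "cognition" else _DRD2_IDX[g.drd2]
    return _COMT_IDX[g.comt], _HTT_IDX[g.httlpr], drd2


_ENDPOINT_IDX = {"panss": 0, "eps": 1, "cognition": 2}


def _loop_signals(
    drug: DrugProfile | None,
    dose_mg: float,
    g: GenotypeState,
    pathology: PathologyParams,
) -> tuple[dict[str, float], "object"]:
    """Striatal signals plus the cortical modulators the loops consume."""
    effects = genotype_effects(g)
    sig = receptor_signals(drug, dose_mg, effects, pathology, "striatal")
    cort = receptor_signals(drug, dose_mg, effects, pathology, "cortical")
    sig["5HT2A"] = cort["5HT2A"]
    sig["5HT1A"] = cort["5HT1A"]
    sig["D1_cortical"] = cort["D1"]
    return sig, effects


def _panss_cell(
    drug: DrugProfile | None,
    dose_mg: float,
    g: GenotypeState,
    cfg: StudyConfigs,
    seed: int,
    untreated_entropy: float,
) -> tuple[float, float]:
    sig, effects = _loop_signals(drug, dose_mg, g, cfg.pathology)
    raster = eff.run_cstc_loop(cfg.loop, sig, effects, cfg.pathology, seed)
    entropy = eff.shannon_entropy(raster)
    return entropy, eff.entropy_to_delta_panss(entropy, untreated_entropy, cfg.panss_cal)


def _eps_cell(
    drug: DrugProfile | None,
    dose_mg: float,
    g: GenotypeState,
    cfg: StudyConfigs,
    seed: int,
) -> tuple[float, float]:
    sig, effects = _loop_signals(drug, dose_mg, g, cfg.pathology)
    trace = mot.run_motor_loop(cfg.motor, sig, effects, cfg.pathology, seed)
    ratio = mot.band_power_ratio(trace)
    return ratio, mot.ratio_to_eps_probability(ratio, cfg.eps_cal)


def _cognition_cell(
    drug: DrugProfile | None,
    dose_mg: float,
    g: GenotypeState,
    cfg: StudyConfigs,
    seed: int,
) -> tuple[float, float]:
    effects = genotype_effects(g)
    sig = receptor_signals(drug, dose_mg, effects, cfg.pathology, "cortical")
    trace = cog.run_working_memory_trial(
        cfg.cortical, cfg.stimulus, sig, effects, seed, cfg.pathology
    )
    span = cog.working_memory_span(trace, cfg.wm_threshold)
    return span, cog.span_to_accuracy(span, cfg.accuracy_cal)


def reference_untreated_entropy(cfg: StudyConfigs, seed: int) -> float:
    """TRN entropy of the untreated pathological reference heterozygote."""
    sig, effects = _loop_signals(None, 0.0, REFERENCE_GENOTYPE, cfg.pathology)
    raster = eff.run_cstc_loop(cfg.loop, sig, effects, cfg.pathology, seed)
    return eff.shannon_entropy(raster)


def run_factorial_study(
    design: StudyDesign,
    configs: StudyConfigs = StudyConfigs(),
    seed: int = 0,
    profiles: Mapping[str, DrugProfile] | None = None,
) -> pd.DataFrame:
    """Run the full factorial and return the tidy outcome table.

    Columns: drug, dose_fraction, dose_mg, genotype, endpoint, seed, raw
    (entropy bits / beta-gamma ratio / span s) and value (delta-PANSS points /
    EPS fraction / 2-back accuracy %).  Placebo rows carry drug="placebo" and
    dose 0.  Cell values are averaged over ``design.n_seeds`` replicates;
    the table is deterministic given the master seed.
    """
    if profiles is None:
        profiles = load_drug_profiles()
    missing = [d for d in design.drugs if d not in profiles]
    if missing:
        raise KeyError(f"no pharmacology profile for: {', '.join(missing)}")

    rows: list[dict] = []
    # entropy of the untreated reference, one per replicate, shared by all cells
    ref_entropy = {
        rep: reference_untreated_entropy(configs, _cell_seed(seed, 0, 99, rep))
        for rep in range(design.n_seeds)
        if "panss" in design.endpoints
    }

    arms: list[tuple[str, DrugProfile | None, float]] = [(PLACEBO, None, 0.0)]
    for name in design.drugs:
        for frac in design.dose_fractions:
            arms.append((name, profiles[name], frac))

    for endpoint in design.endpoints:
        e_idx = _ENDPOINT_IDX[endpoint]
        for arm_idx, (name, profile, frac) in enumerate(arms):
            dose_mg = 0.0 if profile is None else frac * profile.standard_dose
            for g in design.genotypes:
                g_comp = _genotype_seed_components(g, endpoint)
                raws, values = [], []
                for rep in range(design.n_seeds):
                    cell_seed = _cell_seed(seed, e_idx, arm_idx, *g_comp, rep)
                    try:
                        if endpoint == "panss":
                            raw, value = _panss_cell(
                                profile, dose_mg, g, configs, cell_seed, ref_entropy[rep]
                            )
                        elif endpoint == "eps":
                            raw, value = _eps_cell(profile, dose_mg, g, configs, cell_seed)
                        else:
                            raw, value = _cognition_cell(
                                profile, dose_mg, g, configs, cell_seed
                            )
                    except Exception as exc:  # surface the failing cell
                        raise RuntimeError(
                            f"study cell failed: endpoint={endpoint} drug={name} "
                            f"dose_fraction={frac} genotype={g} replicate={rep}"
                        ) from exc
                    raws.append(raw)
                    values.append(value)
                rows.append(
                    {
                        "drug": name,
                        "dose_fraction": 0.0 if profile is None else frac,
                        "dose_mg": dose_mg,
                        "genotype": str(g),
                        "endpoint": endpoint,
                        "seed": seed,
                        "raw": float(np.mean(raws)),
                        "value": float(np.mean(values)),
                    }
                )
    return pd.DataFrame(rows)


def _standard_dose_outcomes(table: pd.DataFrame, endpoint: str) -> pd.DataFrame:
    """Genotype x drug outcome matrix at the standard dose (fraction 1.0)."""
    sub = table[(table["endpoint"] == endpoint) & (table["drug"] != PLACEBO)]
    sub = sub[np.isclose(sub["dose_fraction"], 1.0)]
    if sub.empty:
        raise ValueError(f"no standard-dose rows for endpoint {endpoint!r}")
    mat = sub.pivot_table(index="genotype", columns="drug", values="value")
    if mat.isna().any().any():
        missing = [
            f"{g}/{d}" for g, d in zip(*np.where(mat.isna().values))
        ]
        raise ValueError(f"incomplete outcome table for {endpoint}: {missing[:5]} ...")
    return mat


def single_gene_aggregate(
    table: pd.DataFrame,
    locus: str,
    level: str,
    endpoint: str,
    allele_freq: float = 0.5,
) -> pd.Series:
    """Per-drug outcome for a single-gene subgroup (e.g. COMT MM = ``MM/*/*``).

    Marginalises the two other loci with renormalised Hardy-Weinberg weights,
    exactly as a single-genotype clinical study would average its cohort.
    """
    patterns = {"comt": "{}/*/*", "httlpr": "*/{}/*", "drd2": "*/*/{}"}
    if locus not in patterns:
        raise ValueError(f"locus must be one of {sorted(patterns)}")
    pattern = patterns[locus].format(level)
    mat = _standard_dose_outcomes(table, endpoint)
    out = {}
    for drug in mat.columns:
        outcomes = {GenotypeState.parse(g): v for g, v in mat[drug].items()}
        out[drug] = marginalize(outcomes, pattern, allele_freq)
    return pd.Series(out, name=f"{endpoint}:{pattern}")


@dataclass
class RankTable:
    """Per-genotype drug ranking across the three endpoints.

    ``per_endpoint`` maps endpoint name to a genotype x drug rank matrix
    (each row holds ranks 1-7, average ranks on ties, summing to 28);
    ``totals`` sums the three matrices (each row sums to 84); ``frequency``
    holds Hardy-Weinberg genotype weights; ``best`` maps each genotype to the
    tie-inclusive set of drugs attaining its minimal total rank.
    """

    per_endpoint: dict[str, pd.DataFrame]
    totals: pd.DataFrame
    frequency: pd.Series
    best: dict[str, tuple[str, ...]]

    def validate(self) -> None:
        n = self.totals.shape[1]
        per_endpoint_sum = n * (n + 1) / 2.0
        for endpoint, mat in self.per_endpoint.items():
            if not np.allclose(mat.sum(axis=1), per_endpoint_sum):
                raise AssertionError(f"rank rows for {endpoint} do not sum to {per_endpoint_sum}")
        expected_total = len(self.per_endpoint) * per_endpoint_sum
        if not np.allclose(self.totals.sum(axis=1), expected_total):
            raise AssertionError(f"total rank rows do not sum to {expected_total}")
        if any(len(v) == 0 for v in self.best.values()):
            raise AssertionError("empty minimizer set")


def rank_drugs(
    table: pd.DataFrame,
    allele_freq: float = 0.5,
) -> RankTable:
    """Rank the drugs per genotype from a standard-dose outcome table.

    Each endpoint is first centred on its genotype-frequency-weighted
    cross-drug average (the no-genotype-information expectation), oriented so
    that lower is better (delta-PANSS and EPS ascending, accuracy descending),
    and rank-ordered 1-7 within each genotype with average ranks on ties.
    Totals sum the three endpoint ranks.
    """
    endpoints = [e for e in ENDPOINTS if (table["endpoint"] == e).any()]
    if not endpoints:
        raise ValueError("outcome table contains no known endpoints")
    mats = {e: _standard_dose_outcomes(table, e) for e in endpoints}
    genotype_index = mats[endpoints[0]].index
    weights = np.array(
        [hardy_weinberg_weight(GenotypeState.parse(g), allele_freq) for g in genotype_index]
    )
    weights = weights / weights.sum()

    per_endpoint: dict[str, pd.DataFrame] = {}
    for e, mat in mats.items():
        if not mat.index.equals(genotype_index):
            raise ValueError("endpoints cover different genotype sets")
        centred = mat - (mat.values * weights[:, None]).sum(axis=0)
        oriented = centred * _LOWER_IS_BETTER[e]
        ranks = rankdata(oriented.values, axis=1, method="average")
        per_endpoint[e] = pd.DataFrame(ranks, index=mat.index, columns=mat.columns)

    totals = sum(per_endpoint.values())
    best = {
        g: tuple(totals.columns[np.isclose(row.values, row.min())])
        for g, row in totals.iterrows()
    }
    freq = pd.Series(
        {g: hardy_weinberg_weight(GenotypeState.parse(g), allele_freq) for g in genotype_index},
        name="frequency",
    )
    result = RankTable(per_endpoint=per_endpoint, totals=totals, frequency=freq, best=best)
    result.validate()
    return result


def best_drug_counts(rank_table: RankTable | pd.DataFrame) -> dict[str, int]:
    """Per-drug count of genotypes whose minimal total rank the drug attains.

    Ties count for every minimizer, so the counts sum to at least the number
    of genotypes.  Accepts a RankTable or a bare genotype x drug total-rank
    matrix (e.g. read back from a report file).
    """
    totals = rank_table.totals if isinstance(rank_table, RankTable) else rank_table
    counts = {str(d): 0 for d in totals.columns}
    for _, row in totals.iterrows():
        for d in totals.columns[np.isclose(row.values, row.min())]:
            counts[str(d)] += 1
    return counts


def write_report(
    outcomes: pd.DataFrame,
    rank_table: RankTable,
    outdir: str | Path,
) -> dict[str, Path]:
    """Write the study outputs as CSV files and return their paths.

    ``rank_totals.csv`` mirrors the personalization table: one row per
    genotype with the three locus columns, the Hardy-Weinberg frequency
    (percent, 2 decimals) and the per-drug total ranks.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["outcomes"] = outdir / "outcomes.csv"
    outcomes.to_csv(paths["outcomes"], index=False)

    for endpoint, mat in rank_table.per_endpoint.items():
        p = outdir / f"ranks_{endpoint}.csv"
        mat.to_csv(p)
        paths[f"ranks_{endpoint}"] = p

    totals = rank_table.totals.copy()
    loci = pd.DataFrame(
        [str(g).split("/") for g in totals.index],
        columns=["comt", "httlpr", "drd2"],
        index=totals.index,
    )
    report = pd.concat(
        [
            loci,
            rank_table.frequency.mul(100).round(2).rename("frequency_pct"),
            totals,
        ],
        axis=1,
    )
    paths["rank_totals"] = outdir / "rank_totals.csv"
    report.to_csv(paths["rank_totals"], index=False)

    best = pd.DataFrame(
        {
            "genotype": list(rank_table.best),
            "best_drugs": [";".join(v) for v in rank_table.best.values()],
        }
    )
    paths["best_drugs"] = outdir / "best_drugs.csv"
    best.to_csv(paths["best_drugs"], index=False)
    return paths


def read_rank_totals(path: str | Path) -> pd.DataFrame:
    """Read a ``rank_totals.csv`` back into a genotype x drug total-rank matrix."""
    raw = pd.read_csv(path)
    required = {"comt", "httlpr", "drd2"}
    if not required.issubset(raw.columns):
        raise ValueError("rank totals file must carry the three locus columns")
    index = raw["comt"] + "/" + raw["httlpr"] + "/" + raw["drd2"]
    drugs = [c for c in raw.columns if c not in required | {"frequency_pct"}]
    mat = raw[drugs].copy()
    mat.index = pd.Index(index, name="genotype")
    return mat
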