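"""Readers for the packaged configuration tables.

Three text formats ship with the package and can be overridden by the user:

* ``drugs.tsv`` — drug, receptor, ki_nM, efficacy (one row per drug-receptor
  pair, tab-separated, one header row);
* ``occupancy_anchors.yaml`` — per drug the standard clinical dose and the
  (dose mg, striatal D2 occupancy) anchor list;
* ``genotype_params.yaml`` — per-locus physiological value triples.

Drug affinities/efficacies and occupancy anchors are configuration sourced
from standard pharmacology references; the genotype parameter triples and the
standard doses are study inputs.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from .pharmacology import DrugProfile

#: The seven antipsychotics of the study, in canonical order.
DRUG_ORDER = (
    "aripiprazole",
    "clozapine",
    "haloperidol",
    "olanzapine",
    "paliperidone",
    "quetiapine",
    "risperidone",
)


def _packaged(name: str) -> Path:
    return Path(str(resources.files("neuroqsp").joinpath("data", name)))


def load_drug_profiles(
    affinity_path: str | Path | None = None,
    anchors_path: str | Path | None = None,
) -> dict[str, DrugProfile]:
    """Load the drug pharmacology table and dose anchors into DrugProfiles."""
    affinity_path = _packaged("drugs.tsv") if affinity_path is None else Path(affinity_path)
    anchors_path = (
        _packaged("occupancy_anchors.yaml") if anchors_path is None else Path(anchors_path)
    )
    table = pd.read_csv(affinity_path, sep="\t")
    required = {"drug", "receptor", "ki_nM", "efficacy"}
    if not required.issubset(table.columns):
        raise ValueError(f"drug table must have columns {sorted(required)}")
    with open(anchors_path, encoding="utf-8") as fh:
        anchor_cfg = yaml.safe_load(fh)

    profiles: dict[str, DrugProfile] = {}
    for name, group in table.groupby("drug", sort=False):
        if name not in anchor_cfg:
            raise KeyError(f"no occupancy anchors configured for drug {name!r}")
        cfg = anchor_cfg[name]
        profiles[name] = DrugProfile(
            name=name,
            standard_dose=float(cfg["standard_dose_mg"]),
            affinities=dict(zip(group["receptor"], group["ki_nM"].astype(float))),
            efficacies={
                r: float(e)
                for r, e in zip(group["receptor"], group["efficacy"])
                if float(e) > 0.0
            },
            occupancy_anchors=[(float(d), float(o)) for d, o in cfg["anchors"]],
        )
    return profiles


def load_genotype_params(path: str | Path | None = None) -> dict[str, dict[str, float]]:
    """Load the per-locus genotype parameter triples."""
    path = _packaged("genotype_params.yaml") if path is None else Path(path)
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    expected = {"comt_tau_da_cortical_ms", "httlpr_tau_5ht_ms", "drd2_d2r_scale"}
    if set(cfg) != expected:
        raise ValueError(f"genotype config must define exactly {sorted(expected)}")
    return {k: {kk: float(vv) for kk, vv in v.items()} for k, v in cfg.items()}
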