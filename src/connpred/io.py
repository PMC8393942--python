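"""Dataset directory layout: plain CSV + YAML.

A cohort is written as::

    <dir>/config.yaml            generator configuration (seed included)
    <dir>/covariates.csv         subject_id, age, expertise, group
    <dir>/parcellation.csv       roi_id, roi_name, network
    <dir>/coverage.csv           subjects x ROIs grey-matter flags
    <dir>/effect_map.csv         roi_i, roi_j, target, condition, slope
    <dir>/blocks/<sub>_<cond>_b<k>_{series,nuisance,motion}.csv
    <dir>/ground_truth/<sub>_<cond>.csv

so a run is fully inspectable with standard tools and reloadable without
the generator.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from connpred.simulate import (
    Cohort,
    CohortConfig,
    EffectMap,
    Parcellation,
    SimulatedSession,
    TimeSeriesBlock,
)

__all__ = ["config_hash", "load_cohort", "save_cohort"]


def config_hash(obj) -> str:
    """Stable short hash of a config-like mapping (for provenance logs)."""
    payload = yaml.safe_dump(obj, sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def save_cohort(cohort: Cohort, path: str | Path) -> Path:
    path = Path(path)
    (path / "blocks").mkdir(parents=True, exist_ok=True)
    (path / "ground_truth").mkdir(exist_ok=True)

    with open(path / "config.yaml", "w") as fh:
        yaml.safe_dump(cohort.config.to_dict(), fh, sort_keys=True)
    cohort.covariates.to_csv(path / "covariates.csv", index=False)
    cohort.parcellation.table.to_csv(path / "parcellation.csv", index=False)
    cohort.parcellation.coverage.to_csv(path / "coverage.csv",
                                        index_label="subject_id")
    cohort.effect_map.entries.to_csv(path / "effect_map.csv", index=False)

    for (sid, cond), session in cohort.sessions.items():
        np.savetxt(path / "ground_truth" / f"{sid}_{cond}.csv",
                   session.ground_truth_r, delimiter=",")
        for b in session.blocks:
            stem = path / "blocks" / f"{sid}_{cond}_b{b.block_index}"
            pd.DataFrame(b.data, columns=[str(r) for r in b.roi_ids]) \
                .to_csv(f"{stem}_series.csv", index=False)
            pd.DataFrame(b.nuisance, columns=["wm", "csf"]) \
                .to_csv(f"{stem}_nuisance.csv", index=False)
            pd.DataFrame(b.motion,
                         columns=["tx", "ty", "tz", "rx", "ry", "rz"]) \
                .to_csv(f"{stem}_motion.csv", index=False)
    return path


def load_cohort(path: str | Path) -> Cohort:
    path = Path(path)
    with open(path / "config.yaml") as fh:
        config = CohortConfig.from_dict(yaml.safe_load(fh))
    covariates = pd.read_csv(path / "covariates.csv")
    table = pd.read_csv(path / "parcellation.csv")
    coverage = pd.read_csv(path / "coverage.csv", index_col="subject_id")
    coverage.columns = coverage.columns.astype(int)
    parcellation = Parcellation(table=table, coverage=coverage)
    effect_map = EffectMap(entries=pd.read_csv(path / "effect_map.csv"))

    cohort = Cohort(config=config, covariates=covariates,
                    parcellation=parcellation, effect_map=effect_map)
    roi_ids = table["roi_id"].to_numpy()
    for sid in covariates["subject_id"]:
        for cond in config.conditions:
            gt = np.loadtxt(path / "ground_truth" / f"{sid}_{cond}.csv",
                            delimiter=",")
            blocks = []
            for k in range(1, config.n_blocks + 1):
                stem = path / "blocks" / f"{sid}_{cond}_b{k}"
                data = pd.read_csv(f"{stem}_series.csv").to_numpy()
                nuis = pd.read_csv(f"{stem}_nuisance.csv").to_numpy()
                motion = pd.read_csv(f"{stem}_motion.csv").to_numpy()
                blocks.append(TimeSeriesBlock(
                    data=data, tr=config.tr, subject_id=str(sid),
                    condition=cond, block_index=k, roi_ids=roi_ids,
                    nuisance=nuis, motion=motion))
            cohort.sessions[(str(sid), cond)] = SimulatedSession(
                subject_id=str(sid), condition=cond, blocks=blocks,
                ground_truth_r=gt, roi_ids=roi_ids)
    return cohort
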