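"""End-to-end study orchestration.

``run_full_study`` mirrors the complete analysis: simulate the meditator
and novice cohorts, clean and vectorize both conditions, run the 2 x 2
(target x condition) prediction grid with permutation tests, both confound
controls (residualization and selection-overlap), the novice transfer
test, the edgewise group contrast, and the weight/frequency introspection
products, writing a structured, seed-reproducible report bundle.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from connpred import introspection as intro
from connpred.connectome import assemble_samples
from connpred.io import config_hash
from connpred.preprocess import retain_rois
from connpred.regression import ConnectomeRegression, RegressionConfig
from connpred.simulate import CohortConfig, build_effect_map, generate_cohort

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_full_study"]

CONDITIONS = ("FA", "OM")
TARGETS = ("expertise", "age")


@dataclass
class RunConfig:
    """Configuration of a full study run.

    ``quick()`` gives a reduced grid (fewer repeats/permutations) suited to
    a single CPU; the default mirrors the full protocol.
    """

    seed: int
    out_dir: str = "connpred_run"
    cohort: CohortConfig | None = None
    novice_cohort: CohortConfig | None = None
    regression: RegressionConfig = field(default_factory=RegressionConfig)
    n_perm: int = 1000
    perm_n_repeats: int | None = None  # reduced repeats inside permutations
    consensus_threshold: float = 0.95
    figures: bool = False
    run_permutations: bool = True

    def __post_init__(self) -> None:
        if self.cohort is None:
            self.cohort = CohortConfig.meditators(seed=self.seed)
        if self.novice_cohort is None:
            self.novice_cohort = CohortConfig.novices(seed=self.seed + 1)

    @classmethod
    def quick(cls, seed: int, out_dir: str = "connpred_run", **kw) -> "RunConfig":
        kw.setdefault("regression", RegressionConfig(n_repeats=10, seed=seed))
        kw.setdefault("n_perm", 100)
        kw.setdefault("perm_n_repeats", 5)
        return cls(seed=seed, out_dir=out_dir, **kw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"] = self.cohort.to_dict()
        d["novice_cohort"] = self.novice_cohort.to_dict()
        d["regression"] = self.regression.to_dict()
        return d


def _fit(samples, target, reg: RegressionConfig, seed: int, **overrides):
    return ConnectomeRegression(samples, target=target, config=reg,
                                seed=seed, **overrides).fit()


def run_full_study(config: RunConfig) -> dict:
    """Execute the full analysis grid and write the report bundle.

    Returns the report dictionary (also written as ``report.json`` in the
    output directory alongside edge/network/node tables and, optionally,
    figures).
    """
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    hashed = config.to_dict()
    hashed.pop("out_dir", None)  # artifact location is not part of the science
    chash = config_hash(hashed)
    report: dict = {"config_hash": chash, "seed": config.seed,
                    "config": config.to_dict(), "stages": {}}

    def stage(name):
        logger.info("stage %-22s %6.1f s", name, time.time() - t0)
        report["stages"][name] = round(time.time() - t0, 2)

    try:
        meditators = generate_cohort(config.cohort)
        # novices share the atlas but carry an independently drawn age
        # effect map, so transfer failure is testable against ground truth
        novice_map = build_effect_map(
            meditators.parcellation,
            n_age_edges=config.novice_cohort.n_age_edges,
            n_exp_edges_per_condition=config.novice_cohort.n_exp_edges_per_condition,
            n_shared_exp_edges=config.novice_cohort.n_shared_exp_edges,
            slope_scale=config.novice_cohort.slope_scale,
            seed=config.novice_cohort.seed)
        novice_parc = dataclasses.replace(
            meditators.parcellation,
            coverage=pd.DataFrame(
                True,
                index=list(range(config.novice_cohort.n_subjects)),
                columns=meditators.parcellation.table["roi_id"]))
        novices = generate_cohort(config.novice_cohort,
                                  parcellation=novice_parc,
                                  effect_map=novice_map)
        stage("simulate")

        retained = retain_rois(meditators.parcellation)
        samples = {c: assemble_samples(meditators, c, retained_rois=retained)
                   for c in CONDITIONS}
        novice_samples = {c: assemble_samples(novices, c,
                                              retained_rois=retained)
                          for c in CONDITIONS}
        report["n_retained_rois"] = len(retained)
        report["n_edges"] = samples["FA"].n_edges
        report["n_samples_per_condition"] = samples["FA"].n_samples
        stage("preprocess+connectome")

        results, perms, freqs = {}, {}, {}
        for target in TARGETS:
            for cond in CONDITIONS:
                key = f"{target}_{cond}"
                res = _fit(samples[cond], target, config.regression,
                           config.seed)
                results[key] = res
                freqs[key] = intro.selection_frequency(res)
                entry = {"mse": res.mse, "mse_years": res.mse_years,
                         "cor": res.cor, "n_folds": res.n_folds}
                if config.run_permutations:
                    pt = res.permutation_test(
                        n_perm=config.n_perm,
                        n_repeats=config.perm_n_repeats)
                    perms[key] = pt
                    entry.update(p_cor=pt.p_cor, p_mse=pt.p_mse,
                                 p_cor_bonferroni=pt.p_cor_bonferroni,
                                 p_mse_bonferroni=pt.p_mse_bonferroni)
                report.setdefault("prediction", {})[key] = entry
        stage("prediction_grid")

        # confound control 1: residualize the other covariate
        for target in TARGETS:
            for cond in CONDITIONS:
                res = _fit(samples[cond], target, config.regression,
                           config.seed, confound_mode="residualize")
                report.setdefault("confound_residualized", {})[
                    f"{target}_{cond}"] = {
                    "mse": res.mse, "mse_years": res.mse_years,
                    "cor": res.cor}
        # confound control 2: selection-overlap between the two targets
        for cond in CONDITIONS:
            r, p = intro.frequency_correlation(freqs[f"age_{cond}"],
                                               freqs[f"expertise_{cond}"])
            report.setdefault("frequency_correlations", {})[
                f"age_vs_expertise_{cond}"] = {"r": r, "p": p}
        # condition invariance per target
        for target in TARGETS:
            r, p = intro.frequency_correlation(freqs[f"{target}_FA"],
                                               freqs[f"{target}_OM"])
            report["frequency_correlations"][f"{target}_FA_vs_OM"] = \
                {"r": r, "p": p}
        stage("confound_controls")

        # novice transfer of the age models
        for cond in CONDITIONS:
            tr = results[f"age_{cond}"].transfer(novice_samples[cond],
                                                 target="age")
            report.setdefault("transfer", {})[f"age_{cond}"] = {
                "mse": tr.mse, "mse_std": tr.mse_std, "cor": tr.cor,
                "cor_undefined": tr.cor_undefined}
        # group contrast meditators vs novices
        for cond in CONDITIONS:
            gc = intro.group_contrast(samples[cond], novice_samples[cond])
            gc.to_csv(out / f"group_contrast_{cond}.csv", index=False)
            report.setdefault("group_contrast", {})[cond] = {
                "n_edges_p_lt_05": int((gc["p"] < 0.05).sum()),
                "min_p": float(gc["p"].min())}
        stage("transfer+contrast")

        # introspection bundle
        consensus = {}
        for key, res in results.items():
            cw = intro.consensus_weights(res, config.consensus_threshold)
            consensus[key] = cw
            cw.to_frame(meditators.parcellation).to_csv(
                out / f"consensus_{key}.csv", index=False)
            intro.network_aggregate(cw, meditators.parcellation).to_csv(
                out / f"network_matrix_{key}.csv")
            intro.node_importance(cw, meditators.parcellation).to_csv(
                out / f"node_importance_{key}.csv", index=False)
            report.setdefault("consensus", {})[key] = \
                {"n_edges": int(cw.member.sum())}
        for target in TARGETS:
            sh = intro.shared_edges(consensus[f"{target}_FA"],
                                    consensus[f"{target}_OM"])
            sh.to_csv(out / f"shared_edges_{target}.csv", index=False)
            report.setdefault("shared_edges", {})[target] = int(len(sh))
        pd.DataFrame(freqs).to_csv(out / "selection_frequencies.csv",
                                   index_label="edge")

        if config.figures:
            import matplotlib
            matplotlib.use("Agg")
            import matplotlib.pyplot as plt

            for target in TARGETS:
                ax = intro.plot_frequency_scatter(
                    freqs[f"{target}_FA"], freqs[f"{target}_OM"],
                    "FA", "OM")
                ax.figure.savefig(out / f"freq_{target}_FA_vs_OM.png",
                                  dpi=150, bbox_inches="tight")
                plt.close(ax.figure)
            for key, cw in consensus.items():
                if cw.member.any():
                    ax = intro.plot_network_matrix(
                        intro.network_aggregate(cw, meditators.parcellation))
                    ax.figure.savefig(out / f"network_{key}.png", dpi=150,
                                      bbox_inches="tight")
                    plt.close(ax.figure)
        stage("introspection")
    except Exception as err:
        done = max(report["stages"], default="(none)",
                   key=report["stages"].get) if report["stages"] else "(none)"
        raise RuntimeError(
            f"full-study run failed after stage {done}: {err}") from err

    report["elapsed_s"] = round(time.time() - t0, 2)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=_jsonable)
    return report


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON-serializable: {type(x)}")
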