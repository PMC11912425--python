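"""End-to-end pipeline: simulate -> filter -> fit -> reconstruct -> evaluate.

Driven by a plain YAML config; every run directory receives the resolved
config, all derived seeds, the package version, and a machine-readable
``summary.json``, which together suffice to reproduce the run.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from ._utils import spawn_seed
from .data import exclude_workers, summarize_workers, write_trials, write_images
from .evaluation import (EvaluationReport, chance_corrected, consistency_ceiling,
                         compare_matrices, decode_classes, semantic_comparison,
                         split_half_reliability, within_between_class)
from .model import FitConfig, fit_embedding
from .similarity import behavioral_similarity, marginal_similarity
from .stability import refit_runs, reproducibility
from .synthetic import (WorkerProfile, make_ground_truth, make_semantic_vectors,
                        simulate_repeated_triplets, simulate_trials)

logger = logging.getLogger(__name__)

REQUIRED_SECTIONS = ("synthetic", "fit")


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, dict):
        cfg = dict(path_or_dict)
    else:
        with open(path_or_dict) as fh:
            cfg = yaml.safe_load(fh)
    for section in REQUIRED_SECTIONS:
        if section not in cfg:
            raise ValueError(f"config missing required section: {section!r}")
    cfg.setdefault("seed", 0)
    cfg.setdefault("evaluate", {})
    return cfg


def _worker_mix(mix: dict | None) -> list[tuple[WorkerProfile, float]] | None:
    if not mix:
        return None
    return [(WorkerProfile(kind=k), float(f)) for k, f in mix.items()]


def run_pipeline(config, out_dir) -> dict:
    """Execute the configured pipeline and write all artifacts to ``out_dir``."""
    cfg = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])

    # --- simulate ---------------------------------------------------------
    syn = dict(cfg["synthetic"])
    n_trials = int(syn.pop("n_trials", 50_000))
    lapse = float(syn.pop("lapse_rate", 0.05))
    mix = _worker_mix(syn.pop("worker_mix", None))
    truth = make_ground_truth(seed=spawn_seed(seed, 11), **syn)
    sim = simulate_trials(truth, n_trials=n_trials, lapse_rate=lapse,
                          worker_mix=mix, seed=spawn_seed(seed, 12))
    write_images(truth.images, out / "images.csv")
    write_trials(sim.trials, out / "trials.csv")
    truth.embedding.to_tsv(out / "ground_truth.tsv", sidecar=truth.params)

    # --- filter -----------------------------------------------------------
    summaries = summarize_workers(sim.trials)
    kept, report = exclude_workers(sim.trials, summaries)
    summaries.to_csv(out / "worker_summaries.csv", index=False)
    with open(out / "exclusion.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=2)

    # --- fit --------------------------------------------------------------
    fit_cfg = FitConfig(seed=spawn_seed(seed, 13), **cfg["fit"])
    result = fit_embedding(kept, truth.images, fit_cfg)
    result.embedding.to_tsv(out / "embedding.tsv", sidecar=result.sidecar())

    # --- reconstruct ------------------------------------------------------
    model_sim = marginal_similarity(result.embedding)
    model_sim.to_csv(out / "similarity_model.csv")
    behav_sim = behavioral_similarity(kept, result.embedding.image_ids)
    behav_sim.to_csv(out / "similarity_behavioral.csv")

    # --- evaluate ---------------------------------------------------------
    ev = dict(cfg.get("evaluate", {}))
    repeats = simulate_repeated_triplets(
        truth, n_triplets=int(ev.get("n_repeat_triplets", 300)),
        m_repeats=int(ev.get("m_repeats", 20)), lapse_rate=lapse,
        seed=spawn_seed(seed, 14))
    ceiling = consistency_ceiling(repeats)
    accuracy = 100.0 * result.test_accuracy
    classes = truth.images.set_index("image_id")["class_label"]
    wb = within_between_class(model_sim, classes)
    cmp_res = compare_matrices(model_sim, behav_sim,
                               n_perm=int(ev.get("n_perm", 1000)),
                               seed=spawn_seed(seed, 15))
    sh = split_half_reliability(kept, n_splits=int(ev.get("n_splits", 5)),
                                seed=spawn_seed(seed, 16))
    sem = make_semantic_vectors(truth, coupling=float(ev.get("semantic_coupling", 0.7)),
                                seed=spawn_seed(seed, 17))
    sem_res = semantic_comparison(model_sim, sem, classes)
    dec = decode_classes(result.embedding, classes, seed=spawn_seed(seed, 18))
    report_obj = EvaluationReport(
        ceiling_pct=ceiling,
        model_accuracy_pct=accuracy,
        chance_corrected_pct=chance_corrected(accuracy, ceiling) if ceiling > 50 else float("nan"),
        matrix_r=cmp_res["r"], matrix_ci=(cmp_res["ci_low"], cmp_res["ci_high"]),
        matrix_p=cmp_res["p"],
        split_half_r_corrected=sh["corrected"],
        explainable_variance_pct=(
            100.0 * cmp_res["r"] ** 2 / sh["corrected"] if sh["corrected"] > 0 else float("nan")),
        within_class_mean=wb["within_mean"], between_class_mean=wb["between_mean"],
        class_t=wb["t"], decoding=dec, semantic_r_squared=sem_res["r_squared"],
    )
    report_obj.to_json(out / "evaluation.json")

    # --- stability (optional) --------------------------------------------
    stab_summary = None
    if "stability" in cfg:
        st = dict(cfg["stability"])
        runs = refit_runs(kept, truth.images, fit_cfg,
                          n_runs=int(st.get("n_runs", 5)),
                          master_seed=spawn_seed(seed, 19))
        table = reproducibility(result.embedding, runs)
        table.to_csv(out / "reproducibility.csv", index=False)
        stab_summary = dict(mean_reproducibility=float(np.nanmean(table["reproducibility"])),
                            n_runs=int(st.get("n_runs", 5)))

    # --- provenance + summary --------------------------------------------
    resolved = dict(cfg)
    resolved["_version"] = __version__
    resolved["_derived_seeds"] = {k: spawn_seed(seed, o) for k, o in
                                  [("truth", 11), ("trials", 12), ("fit", 13),
                                   ("repeats", 14), ("compare", 15),
                                   ("split_half", 16), ("semantic", 17),
                                   ("decode", 18), ("stability", 19)]}
    with open(out / "config_resolved.yaml", "w") as fh:
        yaml.safe_dump(resolved, fh, sort_keys=False)
    summary = dict(
        version=__version__, seed=seed,
        n_trials=len(sim.trials), n_trials_kept=len(kept),
        percent_excluded=report.to_dict()["percent_excluded"],
        bayes_accuracy=sim.bayes_accuracy,
        n_dims_retained=result.embedding.n_dims, n_pruned=result.n_pruned,
        test_accuracy_pct=accuracy, ceiling_pct=ceiling,
        chance_corrected_pct=report_obj.chance_corrected_pct,
        matrix_r=cmp_res["r"], split_half_r_corrected=sh["corrected"],
        within_class_mean=wb["within_mean"], between_class_mean=wb["between_mean"],
        semantic_r_squared=sem_res["r_squared"],
        decoding=dec, stability=stab_summary,
    )
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
    return summary
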