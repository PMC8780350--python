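"""Pre-packaged study-scale experiments.

These functions wire the generator, the feature pipeline and the
evaluation layer into the study's headline analyses at the default
cohort scale (11 subjects, 114–118 sessions each), so that drivers,
tests and result scripts all run the identical computation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .evaluation import (
    SubjectDataset,
    compare_models,
    evaluate_cell,
    similarity_histograms,
)
from .ppgfeatures import features_to_frame
from .synthcohort import CohortConfig, PopulationParams, simulate_cohort

__all__ = [
    "cohort_datasets",
    "recovery_population",
    "recovery_config",
    "individual_vs_generalized",
    "scheme_contrast",
]

#: iteration budget for the marginal-likelihood refinement of the GP's
#: kernel in cohort-scale runs; the optimum is reached in well under this
GPR_MAXITER = 30


def cohort_datasets(
    seed: int,
    population: PopulationParams | None = None,
    n_subjects: int = 11,
    **cfg_overrides,
) -> tuple[list[SubjectDataset], pd.DataFrame]:
    """Simulate one cohort, run the waveform feature pipeline, and return
    per-subject datasets plus the tidy feature table."""
    cfg = CohortConfig(seed=seed, n_subjects=n_subjects, **cfg_overrides)
    df = features_to_frame(simulate_cohort(cfg, population))
    datasets = [
        SubjectDataset.from_feature_frame(df, sid)
        for sid in sorted(df["subject_id"].unique())
    ]
    return datasets, df


def recovery_population() -> PopulationParams:
    """Population for the parameter-recovery condition: purely linear
    feature-to-BP map with no slow drift."""
    return PopulationParams(drift_sbp=(0.0, 0.0), drift_dbp=(0.0, 0.0))


def recovery_config(seed: int, n_subjects: int = 4) -> CohortConfig:
    """Cohort configuration for the parameter-recovery condition: a clean
    signal chain (no circadian term, sensor noise, wander or corruption)
    so the only stochastic term left is the 3 mmHg reference noise."""
    return CohortConfig(
        seed=seed,
        n_subjects=n_subjects,
        sessions_min=115,
        sessions_max=115,
        circadian_amp=0.0,
        sensor_noise_sd=0.0,
        wander_amp=0.0,
        corrupt_beat_prob=0.0,
    )


def _datasets_for(seed, population, cache, tag):
    key = (int(seed), tag)
    if cache is not None and key in cache:
        return cache[key]
    datasets, _ = cohort_datasets(int(seed), population)
    if cache is not None:
        cache[key] = datasets
    return datasets


def individual_vs_generalized(
    seeds,
    models=("pls", "lwpls", "gpr"),
    feature_set="set1",
    scheme="scheme_1",
    target="sbp",
    cache: dict | None = None,
) -> dict:
    """Replicate the training-strategy comparison over seeded cohorts.

    For each replicate and model, both strategies are evaluated on the
    same extracted features; per-subject MAEs are paired across
    strategies (subject-by-subject, within replicate) for the t-test.
    """
    per_model: dict[str, dict[str, list]] = {
        m: {"ind": [], "gen": [], "ind_pooled": [], "gen_pooled": []} for m in models
    }
    for seed in seeds:
        datasets = _datasets_for(seed, None, cache, "default")
        for m in models:
            ci = evaluate_cell(
                datasets, m, feature_set, scheme, "individual", target,
                gpr_maxiter=GPR_MAXITER,
            )
            cg = evaluate_cell(
                datasets, m, feature_set, scheme, "generalized", target,
                gpr_maxiter=GPR_MAXITER,
            )
            per_model[m]["ind"].extend(ci.per_subject["mae"].tolist())
            per_model[m]["gen"].extend(cg.per_subject["mae"].tolist())
            per_model[m]["ind_pooled"].append(ci.pooled["mae"])
            per_model[m]["gen_pooled"].append(cg.pooled["mae"])
    out = {}
    for m in models:
        rec = per_model[m]
        cmp = compare_models(rec["ind"], rec["gen"])
        out[m] = {
            "ind_mae": float(np.mean(rec["ind_pooled"])),
            "gen_mae": float(np.mean(rec["gen_pooled"])),
            "p": cmp["p"],
            "individual_lower": cmp["lower"] == "A",
        }
    return out


def scheme_contrast(
    seeds, drift: bool, model="gpr", target="sbp", cache: dict | None = None
) -> dict:
    """Initial-only vs intermittent calibration over seeded cohorts,
    with the slow BP drift at its default or switched off."""
    pop = (
        PopulationParams()
        if drift
        else PopulationParams(drift_sbp=(0.0, 0.0), drift_dbp=(0.0, 0.0))
    )
    gaps, s1, s2 = [], [], []
    for seed in seeds:
        datasets = _datasets_for(seed, pop, cache, "default" if drift else "nodrift")
        c1 = evaluate_cell(
            datasets, model, "set1", "scheme_1", "individual", target,
            gpr_maxiter=GPR_MAXITER,
        )
        c2 = evaluate_cell(
            datasets, model, "set1", "scheme_2", "individual", target,
            gpr_maxiter=GPR_MAXITER,
        )
        s1.append(c1.pooled["mae"])
        s2.append(c2.pooled["mae"])
        gaps.append(c1.pooled["mae"] - c2.pooled["mae"])
    gaps = np.asarray(gaps)
    return {
        "scheme1_mae": float(np.mean(s1)),
        "scheme2_mae": float(np.mean(s2)),
        "gap_mean": float(gaps.mean()),
        "gap_sd": float(gaps.std(ddof=1)),
        "gaps": gaps.tolist(),
    }


def pls_recovery(seed: int, n_subjects: int = 4) -> dict:
    """Individual PLS (2 components, the hr/a02/a25/ri feature set) under
    the linear-map condition, with a day-balanced alternating train/test
    split; reports the mean subject MAE against the irreducible MAE of
    the 3 mmHg reference noise, sqrt(2/pi) * 3."""
    from .ppgfeatures import FEATURE_SETS, FeatureSet
    from .regressors import pls_fit, pls_predict

    cfg = recovery_config(seed, n_subjects=n_subjects)
    df = features_to_frame(simulate_cohort(cfg, recovery_population()))
    cols = list(FEATURE_SETS[FeatureSet.SET1])
    maes = []
    for sid in sorted(df["subject_id"].unique()):
        ds = SubjectDataset.from_feature_frame(df, sid)
        X = ds.frame[cols].to_numpy(float)
        y = ds.frame["sbp_ref"].to_numpy(float)
        train = np.arange(len(y)) % 2 == 0
        m = pls_fit(X[train], y[train], D=2)
        maes.append(float(np.mean(np.abs(pls_predict(m, X[~train]) - y[~train]))))
    irreducible = 3.0 * float(np.sqrt(2.0 / np.pi))
    return {
        "mae_per_subject": maes,
        "mae_mean": float(np.mean(maes)),
        "irreducible_mae": irreducible,
        "ratio": float(np.mean(maes)) / irreducible,
    }


def drift_recovery(cohort) -> dict:
    """OLS of each subject's reference SBP on days-since-start; returns
    slope estimates, standard errors and the generative truths."""
    rows = []
    for subj in cohort:
        days = np.array(
            [
                (r.timestamp - subj.records[0].timestamp).total_seconds() / 86400.0
                for r in subj.records
            ]
        )
        sbp = np.array([r.sbp_ref for r in subj.records])
        A = np.column_stack([np.ones_like(days), days])
        coef, res, *_ = np.linalg.lstsq(A, sbp, rcond=None)
        sigma2 = float(res[0]) / (len(sbp) - 2)
        se = float(np.sqrt(sigma2 * np.linalg.inv(A.T @ A)[1, 1]))
        rows.append(
            {
                "subject_id": subj.subject_id,
                "slope": float(coef[1]),
                "se": se,
                "truth": subj.params.drift_sbp,
                "z": abs(float(coef[1]) - subj.params.drift_sbp) / se,
            }
        )
    return {"subjects": rows, "max_z": max(r["z"] for r in rows)}


def similarity_structure(seed: int, datasets=None) -> dict:
    """Intra- vs inter-subject similarity medians on one default cohort."""
    if datasets is None:
        datasets, _ = cohort_datasets(seed)
    df = pd.concat([d.frame for d in datasets], ignore_index=True)
    out = similarity_histograms(df, max_pairs=50_000, seed=seed)
    return {
        "median_intra": out["median_intra"],
        "median_inter": out["median_inter"],
    }
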