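"""End-to-end study pipeline: simulate (or load) a study bundle, derive the
T2D survival cohort, select per-subtype candidate weights, build the
cross-validated meta-PRS and evaluate it.

This is the programmatic equivalent of running the CLI stages in order,
and the entry point the acceptance script drives.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .evaluation import (CLINICAL_COVARIATES, DEFAULT_ADJUSTMENT, EvalReport,
                         StratifiedReport, evaluate_models,
                         fit_clinical_model, stratify)
from .meta import MetaPRSModel, MetaPRSResults, select_best
from .phenotypes import (CVD_SUBTYPES, DEFAULT_CODE_DEFS, SurvivalCohort,
                         build_cohort, derive_onsets)
from .scoring import PRSVector, WeightSet, clump_threshold, score
from .simulate import SimConfig, StudyBundle, simulate_study
from .survival import CoxPH

__all__ = ["StudyResult", "run_study", "stage1_candidates",
           "stage1_labels"]

DEFAULT_P_THRESHOLDS = (5e-8, 1e-5, 1e-3, 5e-2)


@dataclass
class StudyResult:
    bundle: StudyBundle
    cohort: SurvivalCohort
    selected: dict[str, str]
    meta: MetaPRSResults
    meta_scores: pd.Series
    report: EvalReport
    stratified: StratifiedReport | None


def stage1_labels(bundle: StudyBundle, onsets: pd.DataFrame
                  ) -> tuple[pd.Index, dict[str, np.ndarray]]:
    """Stage-1 cohort and labels.

    The stage-1 population is everyone without a coded CVD onset; cases for
    a subtype are persons flagged as self-reported-only for that subtype,
    controls the remaining record-free population.
    """
    persons = pd.Index(bundle.covariates["person_id"], name="person_id")
    has_record = onsets["CVD"].notna()
    recorded = set(onsets.index[has_record])
    keep = persons[~persons.isin(recorded)]
    labels: dict[str, np.ndarray] = {}
    for subtype in CVD_SUBTYPES:
        flagged = set(bundle.self_reports.loc[
            bundle.self_reports["disease"] == subtype, "person_id"])
        labels[subtype] = np.asarray(keep.isin(flagged), dtype=int)
    return keep, labels


def stage1_candidates(bundle: StudyBundle,
                      p_thresholds: Sequence[float] = DEFAULT_P_THRESHOLDS,
                      r2_max: float = 0.1, window_kb: float = 250.0
                      ) -> dict[str, list[WeightSet]]:
    """P+T candidate weight sets per subtype, one per p-value threshold."""
    out: dict[str, list[WeightSet]] = {}
    for subtype in CVD_SUBTYPES:
        cands = []
        for p_max in p_thresholds:
            ws = clump_threshold(bundle.sumstats[subtype], bundle.genotypes,
                                 p_max=p_max, r2_max=r2_max,
                                 window_kb=window_kb,
                                 label=f"pt_{p_max:g}:{subtype}")
            if len(ws):
                cands.append(ws)
        out[subtype] = cands
    return out


def _true_weightsets(bundle: StudyBundle) -> dict[str, WeightSet]:
    """Oracle weights: the generator's true effects on the allele scale."""
    v = bundle.genotypes.variants
    p = v["eaf"].to_numpy(dtype=float)
    scale = np.sqrt(2 * p * (1 - p))
    out = {}
    for subtype in CVD_SUBTYPES:
        eff = bundle.true_effects[subtype].to_numpy(dtype=float) / scale
        table = pd.DataFrame({
            "variant_id": v["id"].to_numpy(),
            "effect_allele": v["counted_allele"].to_numpy(),
            "other_allele": v["other_allele"].to_numpy(),
            "weight": eff,
        })
        out[subtype] = WeightSet(label=f"true:{subtype}", table=table,
                                 method="oracle")
    return out


def run_study(config: SimConfig | None = None,
              bundle: StudyBundle | None = None,
              components: str = "select",
              p_thresholds: Sequence[float] = DEFAULT_P_THRESHOLDS,
              n_folds: int = 5,
              seed: int | None = None,
              min_follow_up_days: int = 1,
              with_stratified: bool = True,
              extra_models: bool = True,
              clinical_models: bool = True) -> StudyResult:
    """Run the full analysis on a simulated (or provided) study bundle.

    ``components`` chooses how the per-subtype scores are built:
    ``"select"`` runs stage-1 P+T candidate selection by AUC;
    ``"true"`` scores with the generator's true effect sizes (parameter-
    recovery oracle mode). ``seed`` defaults to the bundle config's seed
    and drives the fold assignment.
    """
    if bundle is None:
        if config is None:
            config = SimConfig()
        bundle = simulate_study(config)
    cfg = bundle.config
    if seed is None:
        seed = cfg.seed if cfg is not None else 0
    censor = cfg.censor_date if cfg is not None else "2021-02-05"

    onsets = derive_onsets(bundle.episodes, DEFAULT_CODE_DEFS)
    cohort = build_cohort(onsets, bundle.deaths, bundle.covariates,
                          censor_date=censor,
                          min_follow_up_days=min_follow_up_days)

    # component weight sets
    if components == "true":
        chosen_ws = _true_weightsets(bundle)
        selected = {k: ws.label for k, ws in chosen_ws.items()}
    elif components == "select":
        cands = stage1_candidates(bundle, p_thresholds)
        keep, labels = stage1_labels(bundle, onsets)
        geno = bundle.genotypes
        keep_pos = pd.Index(geno.persons).get_indexer(keep)
        cand_scores = {}
        by_label = {}
        for subtype, wss in cands.items():
            vecs = []
            for ws in wss:
                vec = score(geno, ws)
                by_label[ws.label] = ws
                sub = vec.values[keep_pos]
                vecs.append(PRSVector(person_ids=list(keep), values=sub,
                                      label=ws.label,
                                      n_variants_used=vec.n_variants_used,
                                      n_dropped=vec.n_dropped))
            cand_scores[subtype] = vecs
        selected = select_best(cand_scores, labels)
        chosen_ws = {sub: by_label[lab] for sub, lab in selected.items()}
    else:
        raise ValueError(f"unknown components mode: {components!r}")

    # component scores for the cohort
    geno = bundle.genotypes
    pos = pd.Index(geno.persons).get_indexer(cohort.table.index)
    if np.any(pos < 0):
        raise ValueError("cohort contains persons without genotypes")
    comp = pd.DataFrame(index=cohort.table.index)
    for subtype, ws in chosen_ws.items():
        vec = score(geno, ws)
        comp[subtype] = vec.values[pos]

    model = MetaPRSModel(comp, cohort)
    meta = model.fit(n_folds=n_folds, seed=seed)
    meta_scores = meta.predict(comp)
    folds = meta.fold_assignment

    # per-fold clinical scores and the integrated model
    n = cohort.n
    mvals = meta_scores.to_numpy(dtype=float)
    model_scores: dict[str, np.ndarray] = {"meta": mvals}
    if extra_models:
        for subtype in CVD_SUBTYPES:
            model_scores[subtype] = comp[subtype].to_numpy(dtype=float)
    clin_scores = None
    if clinical_models:
        clin_scores = np.empty((n_folds, n))
        combo_scores = np.empty((n_folds, n))
        clin_X = cohort.covariates(CLINICAL_COVARIATES).to_numpy(dtype=float)
        for f in range(n_folds):
            tr = folds != f
            cfit, _ = fit_clinical_model(cohort.subset(tr))
            clin_scores[f] = cfit.predict_lp(clin_X)
            mz = (mvals - mvals[tr].mean()) / mvals[tr].std()
            X = np.column_stack([mz, clin_X])
            combo = CoxPH(cohort.times[tr], cohort.events[tr], X[tr],
                          names=["meta"] + CLINICAL_COVARIATES).fit()
            combo_scores[f] = combo.predict_lp(X)
        model_scores["clinical"] = clin_scores
        model_scores["meta+clinical"] = combo_scores

    report = evaluate_models(model_scores, cohort, folds)

    strat = None
    if with_stratified:
        if clin_scores is None:
            raise ValueError("stratified analysis requires clinical_models")
        # clinical score for stratification: mean of the per-fold scores
        strat = stratify(mvals, clin_scores.mean(axis=0), cohort)

    return StudyResult(bundle=bundle, cohort=cohort, selected=selected,
                       meta=meta, meta_scores=meta_scores, report=report,
                       stratified=strat)
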