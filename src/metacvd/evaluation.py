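"""Held-out evaluation of polygenic and clinical risk models.

Every headline number is the arithmetic mean of the per-fold values
computed on the five held-out test folds (hazard ratios averaged on the HR
scale, CI bounds averaged bound-wise); the per-fold arrays are kept so that
invariant is checkable. Cox association models are adjusted for age at T2D
onset, sex and the first ten genetic principal components; "PRS + baseline"
AUCs score the linear predictor of a Cox model refit on the training fold
with the score plus those covariates.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .phenotypes import SurvivalCohort
from .survival import CoxPH, CoxFit, auc, km_curve, quantile_incidence

__all__ = [
    "CLINICAL_COVARIATES",
    "DEFAULT_ADJUSTMENT",
    "fit_clinical_model",
    "ModelEval",
    "EvalReport",
    "evaluate_models",
    "CalibrationResult",
    "calibrate",
    "StratifiedReport",
    "stratify",
]

# Clinical risk factors: the overlap of the classic CVD risk equations'
# variable lists (Framingham, pooled cohort equations) with what a T2D
# biobank cohort records, plus glycemia.
CLINICAL_COVARIATES = [
    "age_at_onset", "sex", "bmi", "smoking", "hypertension",
    "tc", "ldl_c", "hdl_c", "tg", "lipid_med", "glucose",
]

DEFAULT_ADJUSTMENT = ["age_at_onset", "sex"] + [f"pc{i}" for i in
                                                range(1, 11)]


def fit_clinical_model(cohort: SurvivalCohort,
                       covariates: Sequence[str] = CLINICAL_COVARIATES
                       ) -> tuple[CoxFit, pd.Series]:
    """Cox model on clinical covariates; returns (fit, risk score).

    The clinical risk score is the linear predictor of the fitted model.
    Must be fitted on a training split only; apply the fit to held-out
    persons via ``fit.predict_lp``. Raises ``KeyError`` naming any missing
    covariate column.
    """
    X = cohort.covariates(covariates)
    fit = CoxPH(cohort.times, cohort.events, X,
                names=list(covariates)).fit()
    lp = pd.Series(fit.predict_lp(X.to_numpy(dtype=float)),
                   index=cohort.table.index, name="clinical_risk")
    return fit, lp


def _as_fold_scores(scores, n: int, n_folds: int) -> np.ndarray:
    """Normalize a score spec to shape (n_folds, n).

    Accepts a single vector (same scores for every fold) or a per-fold
    matrix for scores that must be recomputed on each training split
    (e.g. the clinical model's linear predictor).
    """
    arr = np.asarray(scores, dtype=float)
    if arr.ndim == 1:
        if len(arr) != n:
            raise ValueError("score vector length does not match cohort")
        return np.tile(arr, (n_folds, 1))
    if arr.shape != (n_folds, n):
        raise ValueError(f"per-fold scores must have shape ({n_folds}, {n})")
    return arr


@dataclass
class ModelEval:
    """Per-model evaluation: per-fold arrays plus their means."""

    name: str
    # per-fold arrays
    fold_hr: np.ndarray
    fold_hr_ci: np.ndarray        # (n_folds, 2)
    fold_hr_p: np.ndarray
    fold_auc: np.ndarray
    fold_auc_ci: np.ndarray       # (n_folds, 2)
    fold_auc_full: np.ndarray
    fold_auc_full_ci: np.ndarray  # (n_folds, 2)
    fold_decile_rates: np.ndarray  # (n_folds, q)
    fold_decile_fold: np.ndarray
    fold_tb_hr: np.ndarray
    fold_tb_hr_ci: np.ndarray     # (n_folds, 2)
    km_top: list = field(default_factory=list)     # (times, surv) per fold
    km_bottom: list = field(default_factory=list)

    # headline values == arithmetic means over folds
    @property
    def hr(self) -> float:
        return float(self.fold_hr.mean())

    @property
    def hr_ci(self) -> tuple[float, float]:
        m = self.fold_hr_ci.mean(axis=0)
        return float(m[0]), float(m[1])

    @property
    def auc(self) -> float:
        return float(self.fold_auc.mean())

    @property
    def auc_ci(self) -> tuple[float, float]:
        m = self.fold_auc_ci.mean(axis=0)
        return float(m[0]), float(m[1])

    @property
    def auc_full(self) -> float:
        return float(self.fold_auc_full.mean())

    @property
    def auc_full_ci(self) -> tuple[float, float]:
        m = self.fold_auc_full_ci.mean(axis=0)
        return float(m[0]), float(m[1])

    @property
    def decile_rates(self) -> np.ndarray:
        return self.fold_decile_rates.mean(axis=0)

    @property
    def decile_fold_ratio(self) -> float:
        finite = self.fold_decile_fold[np.isfinite(self.fold_decile_fold)]
        return float(finite.mean()) if len(finite) else float("inf")

    @property
    def top_bottom_hr(self) -> float:
        # NaN folds: extreme-group fit failed (e.g. separation in a small
        # test fold); the headline averages the remaining folds
        return float(np.nanmean(self.fold_tb_hr))

    @property
    def top_bottom_hr_ci(self) -> tuple[float, float]:
        m = np.nanmean(self.fold_tb_hr_ci, axis=0)
        return float(m[0]), float(m[1])


@dataclass
class EvalReport:
    """Cross-validated evaluation of several risk models."""

    models: dict[str, ModelEval]
    n_folds: int
    q: int
    adjustment: list[str]
    ties: str = "breslow"

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, m in self.models.items():
            rows.append({
                "model": name,
                "HR_per_SD": m.hr,
                "HR_lo": m.hr_ci[0],
                "HR_hi": m.hr_ci[1],
                "AUC": m.auc,
                "AUC_lo": m.auc_ci[0],
                "AUC_hi": m.auc_ci[1],
                "AUC_plus_baseline": m.auc_full,
                "decile_fold_ratio": m.decile_fold_ratio,
                "top_bottom_HR": m.top_bottom_hr,
            })
        return pd.DataFrame(rows).set_index("model")

    def to_json(self, path=None) -> str:
        def _enc(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            raise TypeError(type(o))
        payload = {
            "n_folds": self.n_folds,
            "q": self.q,
            "adjustment": self.adjustment,
            "ties": self.ties,
            "models": {
                name: {
                    "headline": {
                        "HR_per_SD": m.hr,
                        "HR_CI": list(m.hr_ci),
                        "AUC": m.auc,
                        "AUC_CI": list(m.auc_ci),
                        "AUC_plus_baseline": m.auc_full,
                        "AUC_plus_baseline_CI": list(m.auc_full_ci),
                        "decile_rates": m.decile_rates.tolist(),
                        "decile_fold_ratio": m.decile_fold_ratio,
                        "top_bottom_HR": m.top_bottom_hr,
                        "top_bottom_HR_CI": list(m.top_bottom_hr_ci),
                    },
                    "per_fold": {
                        "HR": m.fold_hr.tolist(),
                        "HR_CI": m.fold_hr_ci.tolist(),
                        "AUC": m.fold_auc.tolist(),
                        "AUC_full": m.fold_auc_full.tolist(),
                        "decile_rates": m.fold_decile_rates.tolist(),
                        "decile_fold": [
                            None if not np.isfinite(v) else float(v)
                            for v in m.fold_decile_fold],
                        "top_bottom_HR": m.fold_tb_hr.tolist(),
                    },
                }
                for name, m in self.models.items()
            },
        }
        text = json.dumps(payload, indent=2, default=_enc)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def evaluate_models(scores: Mapping[str, np.ndarray],
                    cohort: SurvivalCohort,
                    folds: np.ndarray,
                    adjustment: Sequence[str] = DEFAULT_ADJUSTMENT,
                    q: int = 10,
                    extreme_fraction: float = 0.10,
                    min_test_n: int = 10) -> EvalReport:
    """Evaluate each score on the held-out fifth of every fold.

    ``scores`` maps model name to either one score vector for the whole
    cohort or a per-fold ``(n_folds, n)`` matrix (for scores that depend
    on the training split). For each fold and model this computes, on the
    test fold: the adjusted HR per SD (score standardized to the training
    SD), the score-only AUC, the score+baseline AUC (Cox refit on the
    training fold with score + adjustment covariates), the ``q``-quantile
    incidence vector with its top/bottom fold ratio, and the adjusted HR
    with KM curves contrasting the top and bottom ``extreme_fraction`` of
    the score. Headlines are fold means.
    """
    n = cohort.n
    folds = np.asarray(folds)
    n_folds = int(folds.max()) + 1
    times = cohort.times
    events = cohort.events
    adj = cohort.covariates(adjustment).to_numpy(dtype=float)
    out: dict[str, ModelEval] = {}
    for name, spec in scores.items():
        sc = _as_fold_scores(spec, n, n_folds)
        f_hr = np.empty(n_folds)
        f_hr_ci = np.empty((n_folds, 2))
        f_hr_p = np.empty(n_folds)
        f_auc = np.empty(n_folds)
        f_auc_ci = np.empty((n_folds, 2))
        f_aucf = np.empty(n_folds)
        f_aucf_ci = np.empty((n_folds, 2))
        f_dec = np.empty((n_folds, q))
        f_decf = np.empty(n_folds)
        f_tb = np.empty(n_folds)
        f_tb_ci = np.empty((n_folds, 2))
        km_top, km_bottom = [], []
        for f in range(n_folds):
            te = folds == f
            tr = ~te
            if te.sum() < min_test_n:
                raise ValueError(f"test fold {f} has fewer than "
                                 f"{min_test_n} persons")
            s = sc[f]
            mu, sd = s[tr].mean(), s[tr].std()
            if sd == 0:
                raise ValueError(f"constant score for model {name!r}")
            z = (s - mu) / sd
            # adjusted association on the held-out fold
            X_te = np.column_stack([z[te], adj[te]])
            fit = CoxPH(times[te], events[te], X_te,
                        names=["score"] + list(adjustment)).fit()
            f_hr[f] = np.exp(fit.params[0])
            f_hr_ci[f] = np.exp(fit.conf_int[0])
            f_hr_p[f] = fit.pvalues[0]
            # discrimination
            a = auc(s[te], events[te])
            f_auc[f] = a.auc
            f_auc_ci[f] = a.ci
            X_tr = np.column_stack([z[tr], adj[tr]])
            full = CoxPH(times[tr], events[tr], X_tr,
                         names=["score"] + list(adjustment)).fit()
            lp_te = full.predict_lp(X_te)
            af = auc(lp_te, events[te])
            f_aucf[f] = af.auc
            f_aucf_ci[f] = af.ci
            # quantile incidence
            qi = quantile_incidence(s[te], events[te], q=q)
            f_dec[f] = qi.rates
            f_decf[f] = qi.fold_ratio
            # top vs bottom extreme groups
            order = np.argsort(s[te], kind="stable")
            k = max(1, int(np.floor(te.sum() * extreme_fraction)))
            bot_idx = order[:k]
            top_idx = order[-k:]
            sel = np.concatenate([bot_idx, top_idx])
            grp = np.concatenate([np.zeros(k), np.ones(k)])
            t_sub = times[te][sel]
            e_sub = events[te][sel]
            X_sub = np.column_stack([grp, adj[te][sel]])
            try:
                tb = CoxPH(t_sub, e_sub, X_sub,
                           names=["top_vs_bottom"] + list(adjustment)).fit()
                f_tb[f] = np.exp(tb.params[0])
                f_tb_ci[f] = np.exp(tb.conf_int[0])
            except Exception:
                f_tb[f] = np.nan
                f_tb_ci[f] = (np.nan, np.nan)
            km_top.append(km_curve(times[te][top_idx], events[te][top_idx]))
            km_bottom.append(km_curve(times[te][bot_idx],
                                      events[te][bot_idx]))
        out[name] = ModelEval(
            name=name, fold_hr=f_hr, fold_hr_ci=f_hr_ci, fold_hr_p=f_hr_p,
            fold_auc=f_auc, fold_auc_ci=f_auc_ci, fold_auc_full=f_aucf,
            fold_auc_full_ci=f_aucf_ci, fold_decile_rates=f_dec,
            fold_decile_fold=f_decf, fold_tb_hr=f_tb, fold_tb_hr_ci=f_tb_ci,
            km_top=km_top, km_bottom=km_bottom,
        )
    return EvalReport(models=out, n_folds=n_folds, q=q,
                      adjustment=list(adjustment))


@dataclass
class CalibrationResult:
    """Predicted vs observed risk per decile plus recalibration slope."""

    table: pd.DataFrame   # bin, mean_predicted, observed, n
    slope: float
    intercept: float
    t_star: float
    degenerate: bool = False


def calibrate(scores, cohort: SurvivalCohort, n_bins: int = 10,
              t_star: float | None = None,
              risk_fit: CoxFit | None = None) -> CalibrationResult:
    """Calibration of the score-based Cox risk at the median follow-up.

    Fits a single-covariate Cox model on the standardized score, converts
    it to absolute risk ``1 - exp(-H0(t*) e^lp)`` with the Breslow baseline
    at ``t* = median follow-up`` (capped at the last event time with a
    warning), bins persons by predicted risk and contrasts mean predicted
    risk with observed incidence (one minus Kaplan-Meier at ``t*``) per
    bin. The calibration slope comes from a logistic regression of the
    event indicator on the predicted log-odds.

    ``risk_fit`` supplies an externally fitted single-covariate Cox model
    (with its Breslow baseline) to be calibrated instead of refitting on
    this cohort; the score is standardized on this cohort either way.
    """
    import statsmodels.api as sm

    s = np.asarray(scores, dtype=float)
    times = cohort.times
    events = cohort.events
    if s.std() == 0:
        table = pd.DataFrame({
            "bin": [0], "mean_predicted": [events.mean()],
            "observed": [events.mean()], "n": [len(s)]})
        return CalibrationResult(table=table, slope=np.nan,
                                 intercept=np.nan,
                                 t_star=float(np.median(times)),
                                 degenerate=True)
    z = (s - s.mean()) / s.std()
    fit = (risk_fit if risk_fit is not None
           else CoxPH(times, events, z[:, None], names=["score"]).fit())
    if t_star is None:
        t_star = float(np.median(times))
    last_event = float(times[events == 1].max())
    if t_star > last_event:
        warnings.warn("median follow-up exceeds the last event time; "
                      "using the last event time", stacklevel=2)
        t_star = last_event
    pred = fit.predict_risk(z[:, None], t_star)
    order = np.argsort(pred, kind="stable")
    bins = np.array_split(order, n_bins)
    rows = []
    for b, idx in enumerate(bins):
        t_km, s_km = km_curve(times[idx], events[idx])
        pos = np.searchsorted(t_km, t_star, side="right") - 1
        observed = 1.0 - (s_km[pos] if pos >= 0 else 1.0)
        rows.append({"bin": b, "mean_predicted": float(pred[idx].mean()),
                     "observed": float(observed), "n": len(idx)})
    table = pd.DataFrame(rows)
    eps = 1e-12
    logit = np.log(np.clip(pred, eps, 1 - eps)
                   / np.clip(1 - pred, eps, 1 - eps))
    glm = sm.GLM(events, sm.add_constant(logit),
                 family=sm.families.Binomial()).fit()
    return CalibrationResult(table=table,
                             slope=float(glm.params[1]),
                             intercept=float(glm.params[0]),
                             t_star=t_star)


@dataclass
class StratifiedReport:
    """Onset-age- and sex-stratified performance summary.

    ``proportions`` holds, per onset group, the percentage of CVD cases in
    the four cells {high PRS only, high clinical only, both, neither}
    (summing to 100 within a group). ``arr`` holds the absolute difference
    in CVD incidence between early- and late-onset patients within the
    high-PRS group and within the remaining patients, plus their ratio.
    """

    age_cut: float
    top_fraction: float
    proportions: pd.DataFrame       # index (early, late) x 4 cells, percent
    group_hr: pd.DataFrame          # per onset group: HR per SD + CI + AUC
    arr: dict[str, float]           # arr_high, arr_remaining, ratio
    sex_hr: pd.DataFrame            # per sex: HR per SD + CI + AUC

    def to_json(self, path=None) -> str:
        payload = {
            "age_cut": self.age_cut,
            "top_fraction": self.top_fraction,
            "proportions_pct": self.proportions.to_dict(),
            "group_hr": self.group_hr.to_dict(),
            "arr": self.arr,
            "sex_hr": self.sex_hr.to_dict(),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _group_perf(cohort: SurvivalCohort, score: np.ndarray, mask: np.ndarray,
                adjustment: Sequence[str]) -> dict[str, float]:
    sub_t = cohort.times[mask]
    sub_e = cohort.events[mask]
    s = score[mask]
    z = (s - s.mean()) / s.std()
    adj = cohort.covariates(adjustment).to_numpy(dtype=float)[mask]
    # drop covariates that are constant within the stratum (e.g. sex in a
    # sex stratum)
    keep = adj.std(axis=0) > 0
    X = np.column_stack([z, adj[:, keep]])
    names = ["score"] + [c for c, k in zip(adjustment, keep) if k]
    fit = CoxPH(sub_t, sub_e, X, names=names).fit()
    a = auc(s, sub_e)
    return {
        "HR_per_SD": float(np.exp(fit.params[0])),
        "HR_lo": float(np.exp(fit.conf_int[0, 0])),
        "HR_hi": float(np.exp(fit.conf_int[0, 1])),
        "AUC": a.auc,
        "AUC_lo": a.ci[0],
        "AUC_hi": a.ci[1],
        "n": int(mask.sum()),
        "n_events": int(sub_e.sum()),
    }


def stratify(meta_scores, clinical_scores, cohort: SurvivalCohort,
             age_cut: float = 55.0, top_fraction: float = 0.20,
             adjustment: Sequence[str] = DEFAULT_ADJUSTMENT
             ) -> StratifiedReport:
    """Early- vs late-onset contrast of genetic and clinical risk.

    High-risk thresholds are the upper ``top_fraction`` quantiles of each
    score over the full T2D cohort. Among the CVD cases of each onset
    group (T2D onset age <= ``age_cut`` vs above) the four cells
    {high PRS only, high clinical only, both, neither} are reported as
    percentages; HR per SD and AUC are computed within each onset group
    and each sex; the absolute risk reduction (ARR) is the absolute
    early-late difference in CVD incidence within the high-PRS group and
    within the remaining patients, with their ratio.
    """
    meta = np.asarray(meta_scores, dtype=float)
    clin = np.asarray(clinical_scores, dtype=float)
    if len(meta) != cohort.n or len(clin) != cohort.n:
        raise ValueError("scores must cover the whole cohort")
    age = cohort.table["age_at_onset"].to_numpy(dtype=float)
    events = cohort.events
    early = age <= age_cut
    late = ~early
    if early.sum() == 0 or late.sum() == 0:
        raise ValueError("empty onset-age group")
    thr_meta = np.quantile(meta, 1.0 - top_fraction)
    thr_clin = np.quantile(clin, 1.0 - top_fraction)
    high_prs = meta >= thr_meta
    high_clin = clin >= thr_clin

    prop_rows = {}
    for gname, gmask in (("early", early), ("late", late)):
        cases = gmask & (events == 1)
        n_cases = cases.sum()
        if n_cases == 0:
            raise ValueError(f"no CVD cases in {gname}-onset group")
        cells = {
            "high_prs_only": (cases & high_prs & ~high_clin).sum(),
            "high_clinical_only": (cases & ~high_prs & high_clin).sum(),
            "both": (cases & high_prs & high_clin).sum(),
            "neither": (cases & ~high_prs & ~high_clin).sum(),
        }
        prop_rows[gname] = {k: 100.0 * v / n_cases
                            for k, v in cells.items()}
    proportions = pd.DataFrame(prop_rows).T

    group_hr = pd.DataFrame({
        g: _group_perf(cohort, meta, m, adjustment)
        for g, m in (("early", early), ("late", late))
    }).T

    def _incidence(mask):
        return float(events[mask].mean()) if mask.any() else np.nan

    arr_high = abs(_incidence(early & high_prs) - _incidence(late & high_prs))
    arr_rem = abs(_incidence(early & ~high_prs) - _incidence(late & ~high_prs))
    arr = {
        "arr_high_prs": arr_high,
        "arr_remaining": arr_rem,
        "ratio": float(arr_high / arr_rem) if arr_rem > 0 else float("inf"),
    }

    sex = cohort.table["sex"].to_numpy(dtype=float)
    sex_rows = {}
    for label, m in (("male", sex == 1), ("female", sex == 0)):
        if m.sum() and events[m].sum():
            sex_rows[label] = _group_perf(cohort, meta, m, adjustment)
    sex_hr = pd.DataFrame(sex_rows).T

    return StratifiedReport(age_cut=age_cut, top_fraction=top_fraction,
                            proportions=proportions, group_hr=group_hr,
                            arr=arr, sex_hr=sex_hr)
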