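"""Meta-polygenic-risk-score construction.

The meta-PRS for composite CVD combines the three standardized subtype
scores (CAD, IS, HF) into a single variance-normalized predictor:

    meta_i = (b1*Z_i1 + b2*Z_i2 + b3*Z_i3) / D,
    D = sqrt(b1^2 + b2^2 + b3^2
             + 2 b1 b2 rho12 + 2 b1 b3 rho13 + 2 b2 b3 rho23),

where ``Z_ik`` is subtype score k standardized on the training split,
``b_k`` are Cox log-hazard coefficients of the three standardized scores
for CVD occurrence among T2D patients, and ``rho`` is the Pearson
correlation matrix of the standardized scores. The denominator is exactly
the standard deviation of the numerator given ``rho``, so the meta score
has unit variance on the population that supplied ``b`` and ``rho``.

Training is a two-stage procedure. Stage 1 picks, per subtype, the
best-performing candidate weight set by AUC on a CVD-record-free cohort
whose cases are self-reported-only histories (:func:`select_best`).
Stage 2 (:class:`MetaPRSModel`) runs five-fold cross-validation: within
each fold the scores are standardized on the 4/5 training split, one joint
Cox model of the three standardized components yields ``b``, and ``rho``
is computed on the same split; the stored model carries the per-fold
values and uses their means.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .phenotypes import SurvivalCohort
from .scoring import PRSVector
from .survival import CoxPH, auc

__all__ = ["select_best", "MetaPRSModel", "MetaPRSResults",
           "assign_folds", "combination_denominator"]


def select_best(candidates: Mapping[str, Sequence[PRSVector]],
                labels: Mapping[str, np.ndarray]) -> dict[str, str]:
    """Stage-1 selection: per subtype, the candidate with maximal AUC.

    ``candidates[subtype]`` is a list of :class:`PRSVector` for one
    stage-1 population; ``labels[subtype]`` the binary case labels for the
    same people (cases = self-reported disease history, controls = the
    rest). Ties are broken by candidate order. Returns
    ``{subtype: winning label}``.
    """
    chosen: dict[str, str] = {}
    for subtype, cands in candidates.items():
        if not cands:
            raise ValueError(f"no candidates for subtype {subtype}")
        y = np.asarray(labels[subtype]).astype(int)
        best_label, best_auc = None, -np.inf
        for cand in cands:
            a = auc(cand.values, y).auc
            if a > best_auc:  # strict: first wins ties
                best_label, best_auc = cand.label, a
        chosen[subtype] = best_label
    return chosen


def assign_folds(events: np.ndarray, n_folds: int, seed: int) -> np.ndarray:
    """Seeded fold assignment, stratified on the event indicator.

    Events and non-events are shuffled separately and dealt round-robin, so
    fold sizes are as equal as possible and every fold contains events.
    """
    events = np.asarray(events).astype(int)
    rng = np.random.default_rng(seed)
    folds = np.empty(len(events), dtype=int)
    for value in (0, 1):
        idx = np.flatnonzero(events == value)
        rng.shuffle(idx)
        folds[idx] = np.arange(len(idx)) % n_folds
    return folds


def combination_denominator(beta: np.ndarray, rho: np.ndarray) -> float:
    """``sqrt(beta' rho beta)`` — the SD of the combined numerator."""
    beta = np.asarray(beta, dtype=float)
    rho = np.asarray(rho, dtype=float)
    val = float(beta @ rho @ beta)
    if val <= 0:
        raise ValueError("non-positive combined variance: the combination "
                         "denominator is undefined")
    return float(np.sqrt(val))


@dataclass
class MetaPRSResults:
    """Fitted meta-PRS combination model.

    ``beta``, ``rho``, ``means`` and ``sds`` are the across-fold means;
    the per-fold values are kept for provenance and for the headline-
    equals-fold-mean invariant.
    """

    component_names: tuple[str, ...]
    beta: np.ndarray
    rho: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    denominator: float
    fold_betas: np.ndarray        # (n_folds, 3)
    fold_rhos: np.ndarray         # (n_folds, 3, 3)
    fold_means: np.ndarray        # (n_folds, 3)
    fold_sds: np.ndarray          # (n_folds, 3)
    fold_assignment: np.ndarray   # per-person fold index
    seed: int
    n_folds: int
    mode: str = "joint"
    ties: str = "breslow"
    ridge_used: bool = False

    def predict(self, components: pd.DataFrame) -> pd.Series:
        """Meta score per person from raw component scores.

        ``components`` must have one column per component name. Persons
        with any missing component are dropped with a warning.
        """
        cols = list(self.component_names)
        missing = [c for c in cols if c not in components.columns]
        if missing:
            raise KeyError(f"missing component column(s): {missing}")
        x = components[cols]
        ok = x.notna().all(axis=1)
        if not ok.all():
            warnings.warn(f"dropping {int((~ok).sum())} person(s) with "
                          f"missing component scores", stacklevel=2)
            x = x[ok]
        z = (x.to_numpy(dtype=float) - self.means) / self.sds
        meta = z @ self.beta / self.denominator
        return pd.Series(meta, index=x.index, name="meta_prs")

    def summary(self) -> pd.DataFrame:
        rows = pd.DataFrame(
            {
                "beta (mean of folds)": self.beta,
                "component mean": self.means,
                "component SD": self.sds,
            },
            index=list(self.component_names),
        )
        return rows

    def to_json(self, path=None) -> str:
        payload = {
            "component_names": list(self.component_names),
            "beta": self.beta.tolist(),
            "rho": self.rho.tolist(),
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "denominator": self.denominator,
            "fold_betas": self.fold_betas.tolist(),
            "fold_rhos": self.fold_rhos.tolist(),
            "fold_means": self.fold_means.tolist(),
            "fold_sds": self.fold_sds.tolist(),
            "fold_assignment": self.fold_assignment.tolist(),
            "seed": self.seed,
            "n_folds": self.n_folds,
            "mode": self.mode,
            "ties": self.ties,
            "ridge_used": self.ridge_used,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, path) -> "MetaPRSResults":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            component_names=tuple(d["component_names"]),
            beta=np.asarray(d["beta"]),
            rho=np.asarray(d["rho"]),
            means=np.asarray(d["means"]),
            sds=np.asarray(d["sds"]),
            denominator=float(d["denominator"]),
            fold_betas=np.asarray(d["fold_betas"]),
            fold_rhos=np.asarray(d["fold_rhos"]),
            fold_means=np.asarray(d["fold_means"]),
            fold_sds=np.asarray(d["fold_sds"]),
            fold_assignment=np.asarray(d["fold_assignment"]),
            seed=int(d["seed"]),
            n_folds=int(d["n_folds"]),
            mode=d.get("mode", "joint"),
            ties=d.get("ties", "breslow"),
            ridge_used=bool(d.get("ridge_used", False)),
        )


class MetaPRSModel:
    """Cross-validated meta-PRS combination for CVD among T2D patients.

    Parameters
    ----------
    components : DataFrame
        Raw (unstandardized) component scores, one column per subtype,
        indexed by person id; must cover every person in ``cohort``.
    cohort : SurvivalCohort
        Follow-up times and event indicators.
    mode : {"joint", "marginal"}
        "joint" fits one Cox model with all three standardized components
        (the default: the combination denominator is then exactly the SD of
        the joint linear predictor); "marginal" fits three single-component
        models.
    """

    COLLINEAR_COND = 1e6
    RIDGE = 1e-8

    def __init__(self, components: pd.DataFrame, cohort: SurvivalCohort,
                 component_names: Sequence[str] = ("CAD", "IS", "HF"),
                 mode: str = "joint"):
        self.component_names = tuple(component_names)
        missing = [c for c in self.component_names
                   if c not in components.columns]
        if missing:
            raise KeyError(f"missing component column(s): {missing}")
        comp = components.reindex(cohort.table.index)[
            list(self.component_names)]
        if comp.isna().any().any():
            raise ValueError("components must cover every cohort person")
        self.components = comp
        self.cohort = cohort
        if mode not in ("joint", "marginal"):
            raise ValueError(f"unknown mode: {mode!r}")
        self.mode = mode

    def fit(self, n_folds: int = 5, seed: int = 0) -> MetaPRSResults:
        times = self.cohort.times
        events = self.cohort.events
        x = self.components.to_numpy(dtype=float)
        k = len(self.component_names)
        folds = assign_folds(events, n_folds, seed)
        fold_betas = np.empty((n_folds, k))
        fold_rhos = np.empty((n_folds, k, k))
        fold_means = np.empty((n_folds, k))
        fold_sds = np.empty((n_folds, k))
        ridge_used = False
        for f in range(n_folds):
            tr = folds != f
            if events[tr].sum() < 1:
                raise ValueError(f"training fold {f} has zero events")
            mu = x[tr].mean(axis=0)
            sd = x[tr].std(axis=0)
            if np.any(sd == 0):
                raise ValueError("constant component score in training fold")
            z_tr = (x[tr] - mu) / sd
            rho = np.corrcoef(z_tr, rowvar=False)
            ridge = 0.0
            if np.linalg.cond(rho) > self.COLLINEAR_COND:
                ridge = self.RIDGE
                ridge_used = True
                warnings.warn(
                    "near-collinear component scores: ridge-stabilized "
                    "information matrix in use", stacklevel=2)
            if self.mode == "joint":
                fitres = CoxPH(times[tr], events[tr], z_tr,
                               names=list(self.component_names),
                               ridge=ridge).fit()
                beta = fitres.params
            else:
                beta = np.array([
                    CoxPH(times[tr], events[tr], z_tr[:, [j]],
                          names=[self.component_names[j]]).fit().params[0]
                    for j in range(k)
                ])
            fold_betas[f] = beta
            fold_rhos[f] = rho
            fold_means[f] = mu
            fold_sds[f] = sd
        beta = fold_betas.mean(axis=0)
        rho = fold_rhos.mean(axis=0)
        denom = combination_denominator(beta, rho)
        return MetaPRSResults(
            component_names=self.component_names,
            beta=beta,
            rho=rho,
            means=fold_means.mean(axis=0),
            sds=fold_sds.mean(axis=0),
            denominator=denom,
            fold_betas=fold_betas,
            fold_rhos=fold_rhos,
            fold_means=fold_means,
            fold_sds=fold_sds,
            fold_assignment=folds,
            seed=seed,
            n_folds=n_folds,
            mode=self.mode,
            ridge_used=ridge_used,
        )
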