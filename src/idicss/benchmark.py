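"""Combinatorial survival-learner benchmark.

Mirrors the comparative framework used to vet the iDICss signature: a
registry of survival-model adapters (penalized Cox family, stepwise Cox,
random survival forest, gradient-boosted Cox, survival SVM, supervised
principal components, PLS-Cox, componentwise boosting), every adapter run
alone and every (variable-selector, fitter) ordered pair, each combination
trained on one cohort and scored by Harrell's C on held-out cohorts, the
table sorted by average C-index.

The adapters are native re-implementations around scikit-survival /
lifelines estimators; fidelity to the original R learners (CoxBoost,
plsRcox, SuperPC) is approximate by design — see the methods note.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression
from sklearn.decomposition import PCA
from sklearn.model_selection import KFold
from sksurv.ensemble import (
    ComponentwiseGradientBoostingSurvivalAnalysis,
    GradientBoostingSurvivalAnalysis,
    RandomSurvivalForest,
)
from sksurv.linear_model import CoxnetSurvivalAnalysis, CoxPHSurvivalAnalysis
from sksurv.svm import FastSurvivalSVM
from sksurv.util import Surv

from .evaluate import concordance_index
from .io import CohortBundle
from .profile import zscore_rows
from .risk import _cox_partial_loglik

logger = logging.getLogger("idicss")

Scorer = Callable[[np.ndarray], np.ndarray]


@dataclass
class FitResult:
    scorer: Scorer
    selected: list[str] | None = None  # genes chosen by a selector-capable adapter


@dataclass
class Adapter:
    """One survival learner: fit(X samples x genes, times, events, seed)."""

    name: str
    can_select: bool
    fit: Callable[[pd.DataFrame, np.ndarray, np.ndarray, int], FitResult]


def _surv(times: np.ndarray, events: np.ndarray):
    return Surv.from_arrays(event=events.astype(bool), time=times)


def _linear_scorer(genes: list[str], beta: np.ndarray) -> Scorer:
    def score(X: pd.DataFrame) -> np.ndarray:
        return X[genes].to_numpy() @ beta

    return score


def _coxnet_cv(
    X: np.ndarray,
    times: np.ndarray,
    events: np.ndarray,
    l1_ratio: float,
    seed: int,
    n_folds: int = 5,
    n_alphas: int = 30,
) -> np.ndarray:
    """Coxnet path + CV partial-likelihood deviance (minimum rule); returns beta."""
    y = _surv(times, events)
    path = CoxnetSurvivalAnalysis(l1_ratio=l1_ratio, alpha_min_ratio=0.01, n_alphas=n_alphas)
    path.fit(X, y)
    alphas = path.alphas_
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    dev = np.zeros(len(alphas))
    for tr, _ in kf.split(X):
        model = CoxnetSurvivalAnalysis(l1_ratio=l1_ratio, alphas=alphas)
        model.fit(X[tr], _surv(times[tr], events[tr]))
        for j in range(model.coef_.shape[1]):
            lp = X @ model.coef_[:, j]
            dev[j] += -2.0 * (
                _cox_partial_loglik(lp, times, events)
                - _cox_partial_loglik(lp[tr], times[tr], events[tr])
            )
    final = CoxnetSurvivalAnalysis(l1_ratio=l1_ratio, alphas=alphas)
    final.fit(X, y)
    return final.coef_[:, int(np.argmin(dev))]


def _fit_lasso(X: pd.DataFrame, times, events, seed) -> FitResult:
    beta = _coxnet_cv(X.to_numpy(), times, events, l1_ratio=1.0, seed=seed)
    genes = list(X.columns)
    nz = [g for g, b in zip(genes, beta) if b != 0]
    return FitResult(_linear_scorer(genes, beta), selected=nz or genes[:1])


def _fit_enet(X: pd.DataFrame, times, events, seed) -> FitResult:
    best_beta, best_dev = None, np.inf
    for l1 in (0.1, 0.3, 0.5, 0.7, 0.9):
        beta = _coxnet_cv(X.to_numpy(), times, events, l1_ratio=l1, seed=seed, n_alphas=20)
        lp = X.to_numpy() @ beta
        dev = -2.0 * _cox_partial_loglik(lp, times, events)
        if dev < best_dev:
            best_dev, best_beta = dev, beta
    genes = list(X.columns)
    nz = [g for g, b in zip(genes, best_beta) if b != 0]
    return FitResult(_linear_scorer(genes, best_beta), selected=nz or genes[:1])


def _fit_ridge(X: pd.DataFrame, times, events, seed) -> FitResult:
    model = CoxPHSurvivalAnalysis(alpha=1.0)
    model.fit(X.to_numpy(), _surv(times, events))
    return FitResult(_linear_scorer(list(X.columns), model.coef_))


def _univariate_cox_z(X: pd.DataFrame, times, events) -> pd.Series:
    """|z| of each gene's univariate Cox coefficient (ridge-stabilized)."""
    zs = {}
    y = _surv(times, events)
    for g in X.columns:
        x = X[[g]].to_numpy()
        try:
            m = CoxPHSurvivalAnalysis(alpha=0.01)
            m.fit(x, y)
            # Wald-like statistic from the fitted coefficient and score scale
            lp = x[:, 0] * m.coef_[0]
            zs[g] = abs(m.coef_[0]) * np.std(lp) if np.std(lp) > 0 else abs(m.coef_[0])
        except Exception:
            zs[g] = 0.0
    return pd.Series(zs)


def _fit_stepwise(X: pd.DataFrame, times, events, seed, max_vars: int = 10,
                  prescreen: int = 30) -> FitResult:
    """Forward stepwise Cox by partial-likelihood AIC over a univariate prescreen."""
    strength = _univariate_cox_z(X, times, events)
    pool = list(strength.sort_values(ascending=False).index[:prescreen])
    y = _surv(times, events)
    chosen: list[str] = []
    best_aic = np.inf
    current_beta = np.zeros(0)
    while len(chosen) < max_vars and pool:
        trial_best = None
        for g in pool:
            cols = chosen + [g]
            try:
                m = CoxPHSurvivalAnalysis(alpha=1e-6)
                m.fit(X[cols].to_numpy(), y)
                lp = X[cols].to_numpy() @ m.coef_
                aic = -2 * _cox_partial_loglik(lp, np.asarray(times), np.asarray(events)) + 2 * len(cols)
            except Exception:
                continue
            if trial_best is None or aic < trial_best[0]:
                trial_best = (aic, g, m.coef_)
        if trial_best is None or trial_best[0] >= best_aic - 1e-9:
            break
        best_aic, g, current_beta = trial_best
        chosen.append(g)
        pool.remove(g)
    if not chosen:
        chosen = pool[:1]
        m = CoxPHSurvivalAnalysis(alpha=1e-6)
        m.fit(X[chosen].to_numpy(), y)
        current_beta = m.coef_
    return FitResult(_linear_scorer(chosen, np.asarray(current_beta)), selected=chosen)


def _fit_rsf(X: pd.DataFrame, times, events, seed) -> FitResult:
    model = RandomSurvivalForest(
        n_estimators=100, min_samples_leaf=10, n_jobs=1, random_state=seed
    )
    model.fit(X.to_numpy(), _surv(times, events))
    cols = list(X.columns)
    return FitResult(lambda Z: model.predict(Z[cols].to_numpy()))


def _fit_gbm(X: pd.DataFrame, times, events, seed) -> FitResult:
    model = GradientBoostingSurvivalAnalysis(n_estimators=100, random_state=seed)
    model.fit(X.to_numpy(), _surv(times, events))
    cols = list(X.columns)
    return FitResult(lambda Z: model.predict(Z[cols].to_numpy()))


def _fit_coxboost(X: pd.DataFrame, times, events, seed) -> FitResult:
    model = ComponentwiseGradientBoostingSurvivalAnalysis(n_estimators=200, random_state=seed)
    model.fit(X.to_numpy(), _surv(times, events))
    beta = np.asarray(model.coef_)[-X.shape[1]:] if len(model.coef_) > X.shape[1] else np.asarray(model.coef_)
    genes = list(X.columns)
    nz = [g for g, b in zip(genes, beta) if b != 0]
    cols = genes
    return FitResult(lambda Z: model.predict(Z[cols].to_numpy()), selected=nz or genes[:1])


def _fit_svm(X: pd.DataFrame, times, events, seed) -> FitResult:
    model = FastSurvivalSVM(max_iter=200, random_state=seed)
    model.fit(X.to_numpy(), _surv(times, events))
    cols = list(X.columns)
    return FitResult(lambda Z: model.predict(Z[cols].to_numpy()))


def _fit_superpc(X: pd.DataFrame, times, events, seed, n_screen: int = 20,
                 n_pc: int = 2) -> FitResult:
    strength = _univariate_cox_z(X, times, events)
    screened = list(strength.sort_values(ascending=False).index[:n_screen])
    pca = PCA(n_components=min(n_pc, len(screened)), random_state=seed)
    comps = pca.fit_transform(X[screened].to_numpy())
    cox = CoxPHSurvivalAnalysis(alpha=1e-4)
    cox.fit(comps, _surv(times, events))

    def score(Z: pd.DataFrame) -> np.ndarray:
        return pca.transform(Z[screened].to_numpy()) @ cox.coef_

    return FitResult(score, selected=screened)


def _deviance_residuals(times: np.ndarray, events: np.ndarray) -> np.ndarray:
    """Deviance residuals of the null Cox model (Nelson-Aalen baseline)."""
    order = np.argsort(times, kind="stable")
    n = len(times)
    at_risk = n - np.arange(n)
    d = events[order]
    haz = d / at_risk
    cumhaz_sorted = np.cumsum(haz)
    cumhaz = np.empty(n)
    cumhaz[order] = cumhaz_sorted
    mart = events - cumhaz
    # dev = sign(m) * sqrt(-2 * (m + d * log(d - m))), with d*log(d-m) = 0 when d = 0
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(events == 1, np.log(np.maximum(events - mart, 1e-12)), 0.0)
    dev = np.sign(mart) * np.sqrt(np.maximum(-2.0 * (mart + events * term), 0.0))
    return dev


def _fit_plscox(X: pd.DataFrame, times, events, seed, n_comp: int = 2) -> FitResult:
    resid = _deviance_residuals(np.asarray(times, float), np.asarray(events, int))
    pls = PLSRegression(n_components=min(n_comp, X.shape[1]))
    pls.fit(X.to_numpy(), resid)
    scores = pls.transform(X.to_numpy())
    cox = CoxPHSurvivalAnalysis(alpha=1e-4)
    cox.fit(scores, _surv(times, events))

    cols = list(X.columns)

    def score(Z: pd.DataFrame) -> np.ndarray:
        return pls.transform(Z[cols].to_numpy()) @ cox.coef_

    return FitResult(score)


def default_registry() -> dict[str, Adapter]:
    """The ten adapter families of the combinatorial framework."""
    return {
        a.name: a
        for a in [
            Adapter("Lasso", True, _fit_lasso),
            Adapter("Enet", True, _fit_enet),
            Adapter("Ridge", False, _fit_ridge),
            Adapter("StepwiseCox", True, _fit_stepwise),
            Adapter("CoxBoost", True, _fit_coxboost),
            Adapter("RSF", False, _fit_rsf),
            Adapter("GBM", False, _fit_gbm),
            Adapter("SurvivalSVM", False, _fit_svm),
            Adapter("SuperPC", True, _fit_superpc),
            Adapter("plsCox", False, _fit_plscox),
        ]
    }


@dataclass(frozen=True)
class Combination:
    selector: str | None
    fitter: str

    @property
    def label(self) -> str:
        return self.fitter if self.selector is None else f"{self.selector}+{self.fitter}"


def enumerate_ml_combinations(registry: dict[str, Adapter]) -> list[Combination]:
    """Every single adapter plus every ordered (selector, fitter != selector) pair."""
    if not registry:
        raise ValueError("empty adapter registry")
    names = list(registry)
    combos = [Combination(None, n) for n in names]
    for sel in names:
        if not registry[sel].can_select:
            continue
        combos.extend(Combination(sel, fit) for fit in names if fit != sel)
    return combos


def _prepare(bundle: CohortBundle, genes: list[str]) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    present = [g for g in genes if g in set(bundle.expression.genes)]
    X = zscore_rows(bundle.expression.data.loc[present]).T  # samples x genes
    clin = bundle.clinical.data.loc[X.index]
    return X, clin["os_time"].to_numpy(float), clin["os_event"].to_numpy(int)


def run_benchmark(
    combinations: Sequence[Combination],
    registry: dict[str, Adapter],
    train: CohortBundle,
    validations: Sequence[CohortBundle],
    genes: list[str],
    seed: int = 0,
) -> pd.DataFrame:
    """Train each combination on ``train`` and report per-cohort Harrell's C.

    Each row: combination label, C-index per validation cohort and the
    average; sorted descending by average. Failed fits are recorded as NaN
    rows, not raised. Adapter score orientation is fixed on the training
    cohort (flipped when training C < 0.5) so that higher always means
    higher risk.
    """
    if not validations:
        raise ValueError("need at least one validation cohort")
    shared = set(genes)
    for cohort in (train, *validations):
        shared &= set(cohort.expression.genes)
    genes = [g for g in genes if g in shared]
    X_tr, t_tr, e_tr = _prepare(train, genes)
    rows = []
    for i, combo in enumerate(sorted(combinations, key=lambda c: c.label)):
        combo_seed = (seed + 7919 * i) % (2**31 - 1)
        row: dict[str, float | str] = {"combination": combo.label}
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cols = list(X_tr.columns)
                if combo.selector is not None:
                    sel = registry[combo.selector].fit(X_tr, t_tr, e_tr, combo_seed)
                    cols = sel.selected or cols
                fitted = registry[combo.fitter].fit(X_tr[cols], t_tr, e_tr, combo_seed)
                train_c = concordance_index(fitted.scorer(X_tr), t_tr, e_tr)
                flip = -1.0 if train_c < 0.5 else 1.0
                cs = []
                for j, cohort in enumerate(validations):
                    X_v, t_v, e_v = _prepare(cohort, genes)
                    c = concordance_index(flip * fitted.scorer(X_v), t_v, e_v)
                    row[f"cohort_{j + 1}"] = c
                    cs.append(c)
                row["average"] = float(np.mean(cs))
        except Exception as exc:  # adapter failure is a result, not a crash
            logger.warning("combination %s failed: %s", combo.label, exc)
            for j in range(len(validations)):
                row.setdefault(f"cohort_{j + 1}", np.nan)
            row["average"] = np.nan
        rows.append(row)
    table = pd.DataFrame(rows).set_index("combination")
    return table.sort_values("average", ascending=False, kind="stable", na_position="last")
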