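"""The iDICss gene-signature risk model.

Candidate genes are the differentially expressed genes between the two iDIC
subgroups (rank-sum test, BH-adjusted q < 0.05 and |log2 fold change| >= 1 by
default). An L1-penalized Cox proportional-hazards model on the z-scored
candidate expression, with the penalty chosen by cross-validated
partial-likelihood deviance (minimum rule), yields the signature: the genes
with nonzero coefficients. The score of a sample is

    iDICss(s) = sum_g beta_g * z_g(s)

with z the gene-wise within-cohort z-score. Samples are stratified at the
training-cohort median (ties go to "low"; the threshold is frozen at
training time and reused unchanged on validation cohorts).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

from .io import ClinicalTable, GeneExpressionMatrix
from .profile import SubgroupAssignment, rank_sum_test, zscore_rows
from .select import bh_adjust

logger = logging.getLogger("idicss")

DEFAULT_Q_MAX = 0.05
DEFAULT_FC_MIN = 1.0
DEFAULT_N_FOLDS = 10


@dataclass
class GeneSignature:
    """Gene -> Cox coefficient map plus training metadata."""

    coefficients: dict[str, float]
    penalty: float = float("nan")
    n_folds: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        self.coefficients = {g: float(b) for g, b in self.coefficients.items() if b != 0.0}
        if not self.coefficients:
            raise ValueError("signature must contain at least one nonzero coefficient")

    @property
    def genes(self) -> list[str]:
        return list(self.coefficients)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene": self.genes, "beta": [self.coefficients[g] for g in self.genes]}
        )


@dataclass
class RiskScore:
    """Per-sample iDICss values, frozen threshold and low/high groups."""

    values: pd.Series
    threshold: float
    groups: pd.Series = field(init=False)

    def __post_init__(self) -> None:
        self.groups = pd.Series(
            np.where(self.values > self.threshold, "high", "low"),
            index=self.values.index,
            name="risk_group",
        )


def differential_genes(
    expr: GeneExpressionMatrix,
    subgroups: SubgroupAssignment,
    q_max: float = DEFAULT_Q_MAX,
    fc_min: float = DEFAULT_FC_MIN,
) -> pd.DataFrame:
    """Per-gene rank-sum test clusterB vs clusterA with BH correction.

    log2FC is the mean expression difference (B minus A) on the log scale.
    Candidates satisfy q < q_max and |log2FC| >= fc_min.
    """
    a = subgroups.samples_in("clusterA")
    b = subgroups.samples_in("clusterB")
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each cluster needs at least 3 samples")
    A = expr.data.loc[:, a].to_numpy()
    B = expr.data.loc[:, b].to_numpy()
    log2fc = B.mean(axis=1) - A.mean(axis=1)
    pvals = np.empty(expr.data.shape[0])
    for i in range(expr.data.shape[0]):
        pvals[i], _ = rank_sum_test(B[i], A[i])
    q = bh_adjust(pvals)
    table = pd.DataFrame(
        {"gene": expr.genes, "log2fc": log2fc, "p": pvals, "q": q}
    ).set_index("gene")
    table["candidate"] = (table["q"] < q_max) & (table["log2fc"].abs() >= fc_min)
    return table


def _cox_partial_loglik(lp: np.ndarray, times: np.ndarray, events: np.ndarray) -> float:
    """Breslow partial log-likelihood of a linear predictor."""
    order = np.argsort(times, kind="stable")
    lp, times, events = lp[order], times[order], events[order]
    # risk-set log-sum-exp, computed from the tail
    exp_lp = np.exp(lp - lp.max())
    rev_cumsum = np.cumsum(exp_lp[::-1])[::-1]
    ll = 0.0
    i = 0
    n = len(times)
    while i < n:
        j = i
        while j < n and times[j] == times[i]:
            j += 1
        at_risk = np.log(rev_cumsum[i]) + lp.max()
        for idx in range(i, j):
            if events[idx] == 1:
                ll += lp[idx] - at_risk
        i = j
    return ll


def fit_lasso_cox(
    expr: GeneExpressionMatrix,
    clinical: ClinicalTable,
    candidates: list[str],
    n_folds: int = DEFAULT_N_FOLDS,
    seed: int = 0,
    *,
    penalty_rule: str = "1se",
    min_samples: int = 30,
    min_events: int = 10,
) -> GeneSignature:
    """L1-penalized Cox on z-scored candidate expression.

    The penalty path comes from :class:`CoxnetSurvivalAnalysis`; the value is
    chosen by ``n_folds``-fold cross-validated partial-likelihood deviance.
    ``penalty_rule`` is "1se" (default: the strongest penalty within one
    standard error of the CV minimum, which controls spurious inclusions) or
    "min" (the CV minimum itself, which yields denser signatures). The model
    is refit on the full cohort at the chosen penalty. Deterministic given
    ``seed`` (it fixes the CV partition).
    """
    if penalty_rule not in ("1se", "min"):
        raise ValueError("penalty_rule must be '1se' or 'min'")
    samples = [s for s in expr.samples if s in set(clinical.samples)]
    clin = clinical.data.loc[samples]
    times = clin["os_time"].to_numpy(dtype=float)
    events = clin["os_event"].to_numpy(dtype=int)
    if len(samples) < min_samples:
        raise ValueError(f"need >= {min_samples} samples")
    if events.sum() < min_events:
        raise ValueError(f"need >= {min_events} events")
    genes = [g for g in candidates if g in set(expr.genes)]
    sub = expr.data.loc[genes, samples]
    keep = sub.std(axis=1, ddof=1) > 0
    if (~keep).any():
        logger.info("dropping %d constant candidate genes", int((~keep).sum()))
        sub = sub.loc[keep]
    genes = list(sub.index)
    if len(genes) < 2:
        raise ValueError("need >= 2 usable candidate genes")
    X = zscore_rows(sub).to_numpy().T  # samples x genes
    y = Surv.from_arrays(event=events.astype(bool), time=times)

    path = CoxnetSurvivalAnalysis(l1_ratio=1.0, alpha_min_ratio=0.01, n_alphas=50)
    path.fit(X, y)
    alphas = path.alphas_

    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    deviance = np.zeros((n_folds, len(alphas)))
    for f, (tr, te) in enumerate(kf.split(X)):
        model = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=alphas, fit_baseline_model=False)
        model.fit(X[tr], y[tr])
        coefs = model.coef_  # genes x n_alphas
        for j in range(coefs.shape[1]):
            lp_all = X @ coefs[:, j]
            # held-out contribution: full-data loglik minus training loglik (V&VH)
            ll_full = _cox_partial_loglik(lp_all, times, events)
            ll_train = _cox_partial_loglik(lp_all[tr], times[tr], events[tr])
            deviance[f, j] = -2.0 * (ll_full - ll_train)
    mean_dev = deviance.mean(axis=0)
    best = int(np.argmin(mean_dev))
    if penalty_rule == "1se":
        se = float(deviance.std(axis=0, ddof=1)[best] / np.sqrt(n_folds))
        # alphas are descending: the first index within one SE of the minimum
        best = int(np.flatnonzero(mean_dev <= mean_dev[best] + se)[0])
    alpha = float(alphas[best])

    final = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=alphas, fit_baseline_model=False)
    final.fit(X, y)
    beta = final.coef_[:, best]
    coefficients = {g: float(b) for g, b in zip(genes, beta) if b != 0.0}
    if not coefficients:
        # minimum-rule penalty emptied the model; take the densest penalty instead
        beta = final.coef_[:, -1]
        coefficients = {g: float(b) for g, b in zip(genes, beta) if b != 0.0}
    return GeneSignature(coefficients, penalty=alpha, n_folds=n_folds, seed=seed)


def score_idicss(
    expr: GeneExpressionMatrix,
    signature: GeneSignature,
    threshold: float | None = None,
) -> RiskScore:
    """Score a cohort with a signature; genes are z-scored within the cohort.

    Signature genes missing from the expression matrix contribute 0 (logged);
    fewer than 50% present is an error. Without a supplied (frozen) threshold
    the cohort median is used; group = "high" iff value > threshold.
    """
    present = [g for g in signature.genes if g in set(expr.genes)]
    if len(present) < 0.5 * len(signature.genes):
        raise ValueError(
            f"only {len(present)}/{len(signature.genes)} signature genes present"
        )
    missing = set(signature.genes) - set(present)
    if missing:
        logger.info("signature genes absent from cohort (contribute 0): %s", sorted(missing))
    z = zscore_rows(expr.data.loc[present])
    beta = np.array([signature.coefficients[g] for g in present])
    values = pd.Series(beta @ z.to_numpy(), index=expr.samples, name="idicss")
    if threshold is None:
        threshold = float(values.median())
    return RiskScore(values=values, threshold=float(threshold))
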