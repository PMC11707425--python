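"""Survival and response evaluation: Kaplan-Meier / log-rank comparisons,
Harrell's concordance, response AUC, classification metrics, time-dependent
AUC, single-gene / gene-pair comparator baselines, and the cell-line drug
sensitivity screen.

Orientation convention: iDICss is a *risk* score — higher values mean worse
prognosis and lower response probability. Metrics that need a direction
(`response_auc`, `time_dependent_auc`) take the score as given; callers
evaluating iDICss against response pass ``-score`` so that an informative
score maps to AUC >= 0.5, and the orientation used is recorded in the
returned report.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from sksurv.metrics import cumulative_dynamic_auc
from sksurv.util import Surv

from .io import GeneExpressionMatrix
from .profile import rank_sum_test, zscore_rows
from .select import bh_adjust

RESPONDER_CATEGORIES = frozenset({"CR", "PR", "responder", "Responder", "R"})

DEFAULT_HORIZON_YEARS = (1.0, 3.0, 5.0)
DAYS_PER_YEAR = 365.25


@dataclass
class SurvivalComparison:
    """Kaplan-Meier curves per group plus the log-rank test."""

    curves: dict[str, pd.DataFrame]  # group -> columns time, survival, at_risk
    statistic: float
    p_value: float


@dataclass
class PerformanceReport:
    """Discrimination and classification metrics for one cohort."""

    c_index: float | None = None
    response_auc: float | None = None
    auc_orientation: str = "lower score predicts response"
    time_dependent_auc: dict[float, float] = field(default_factory=dict)
    classification: dict[str, float | None] = field(default_factory=dict)
    logrank_p: float | None = None

    def to_series(self) -> pd.Series:
        out: dict[str, float | None] = {
            "c_index": self.c_index,
            "response_auc": self.response_auc,
            "logrank_p": self.logrank_p,
        }
        for t, auc in self.time_dependent_auc.items():
            out[f"auc_at_{t:g}"] = auc
        out.update(self.classification)
        return pd.Series(out, dtype=float)


def km_logrank(
    times: np.ndarray, events: np.ndarray, groups: np.ndarray
) -> SurvivalComparison:
    """Product-limit survival curves per group and the log-rank test.

    Two groups give the classical 1-df chi-square; more groups give the
    k-1 df multivariate statistic.
    """
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    curves: dict[str, pd.DataFrame] = {}
    any_event = False
    for lab in labels:
        mask = groups == lab
        if mask.sum() == 0:
            raise ValueError(f"group {lab!r} has zero subjects")
        if events[mask].sum() > 0:
            any_event = True
        kmf = KaplanMeierFitter()
        kmf.fit(times[mask], events[mask])
        tbl = kmf.event_table
        curves[str(lab)] = pd.DataFrame(
            {
                "time": kmf.survival_function_.index.to_numpy(),
                "survival": kmf.survival_function_.iloc[:, 0].to_numpy(),
                "at_risk": tbl["at_risk"].reindex(
                    kmf.survival_function_.index, method="ffill"
                ).to_numpy(),
            }
        )
    if not any_event:
        raise ValueError("no events in any group")
    res = multivariate_logrank_test(times, groups, events)
    return SurvivalComparison(
        curves=curves,
        statistic=float(res.test_statistic),
        p_value=float(res.p_value),
    )


def concordance_index(scores, times, events) -> float:
    """Harrell's C for a risk score.

    Comparable pairs are those where the shorter observed time ends in an
    event; a pair is concordant when the shorter-time subject has the higher
    score, and score ties count 0.5. Pairs tied on time are not comparable.
    """
    scores = np.asarray(scores, float)
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    diff_t = times[:, None] - times[None, :]  # t_i - t_j
    comparable = (diff_t < 0) & (events[:, None] == 1)  # i fails first
    n_comp = comparable.sum()
    if n_comp == 0:
        raise ValueError("no comparable pairs")
    diff_s = scores[:, None] - scores[None, :]
    concordant = (diff_s > 0)[comparable].sum()
    tied = (diff_s == 0)[comparable].sum()
    return float((concordant + 0.5 * tied) / n_comp)


def response_auc(scores, labels) -> float:
    """AUROC that a higher score predicts the positive (responder) class.

    Equivalent to the Mann-Whitney U statistic divided by n1*n0; ties in the
    score contribute 0.5.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels).astype(bool)
    n1, n0 = int(labels.sum()), int((~labels).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(scores)
    u = ranks[labels].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n0))


def dichotomize_response(response: pd.Series) -> pd.Series:
    """CR/PR (or explicit responder labels) -> True, everything else False."""
    return response.astype(str).isin(RESPONDER_CATEGORIES)


def classification_metrics(
    scores, labels, threshold: float | None = None, *, positive_below: bool = True
) -> dict[str, float | None]:
    """Confusion-matrix metrics at a score threshold (default: median score).

    ``positive_below`` predicts the positive class for scores <= threshold
    (the iDICss orientation: low risk -> responder). Metrics whose
    denominator is zero are returned as None rather than NaN.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels).astype(bool)
    if threshold is None:
        threshold = float(np.median(scores))
    pred = scores <= threshold if positive_below else scores > threshold
    tp = int((pred & labels).sum())
    fp = int((pred & ~labels).sum())
    fn = int((~pred & labels).sum())
    tn = int((~pred & ~labels).sum())

    def ratio(num: int, den: int) -> float | None:
        return num / den if den > 0 else None

    sens = ratio(tp, tp + fn)
    spec = ratio(tn, tn + fp)
    ppv = ratio(tp, tp + fp)
    npv = ratio(tn, tn + fn)
    f1 = ratio(2 * tp, 2 * tp + fp + fn)
    acc = ratio(tp + tn, tp + fp + fn + tn)
    return {
        "sensitivity": sens,
        "specificity": spec,
        "ppv": ppv,
        "npv": npv,
        "f1": f1,
        "accuracy": acc,
        "tp": tp,
        "fp": fp,
        "fn": fn,
        "tn": tn,
    }


def time_dependent_auc(
    scores, times, events, horizons
) -> dict[float, float]:
    """Cumulative/dynamic AUC(t) with inverse-probability-of-censoring
    weights from the Kaplan-Meier censoring estimate. Higher score = higher
    risk."""
    scores = np.asarray(scores, float)
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    horizons = np.atleast_1d(np.asarray(horizons, float))
    if (horizons >= times.max()).any() or (horizons <= times.min()).any():
        raise ValueError("horizons must lie strictly inside the follow-up range")
    y = Surv.from_arrays(event=events.astype(bool), time=times)
    aucs, _ = cumulative_dynamic_auc(y, y, scores, horizons)
    return {float(t): float(a) for t, a in zip(horizons, np.atleast_1d(aucs))}


# ---------------------------------------------------------------------------
# Comparator baselines
# ---------------------------------------------------------------------------


def baseline_scores(
    expr: GeneExpressionMatrix,
    single_genes: dict[str, str] | None = None,
    gene_pairs: dict[str, list[tuple[str, str]]] | None = None,
) -> pd.DataFrame:
    """Simple published-marker style baselines.

    Single-gene baselines are z-scored expression of the named gene (e.g.
    PD-L1 = CD274); gene-pair baselines count pairs (a, b) with
    expr(a) > expr(b). Baselines whose genes are missing are skipped.
    """
    out: dict[str, pd.Series] = {}
    genes = set(expr.genes)
    for name, gene in (single_genes or {}).items():
        if gene not in genes:
            continue
        out[name] = zscore_rows(expr.data.loc[[gene]]).iloc[0]
    for name, pairs in (gene_pairs or {}).items():
        usable = [(a, b) for a, b in pairs if a in genes and b in genes]
        if not usable:
            continue
        score = np.zeros(len(expr.samples))
        for a, b in usable:
            score += (expr.data.loc[a].to_numpy() > expr.data.loc[b].to_numpy()).astype(float)
        out[name] = pd.Series(score, index=expr.samples)
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Drug sensitivity screen
# ---------------------------------------------------------------------------


def drug_screen(
    cellline_scores: pd.Series,
    ic50: pd.DataFrame,
    rho_min: float = 0.3,
    q_max: float = 0.05,
) -> pd.DataFrame:
    """Spearman screen of drug IC50 against the cell-line iDICss.

    One row per drug: rho, p, BH q over drugs, candidate flag
    (|rho| >= rho_min and q < q_max), and a rank-sum p comparing IC50 between
    high- and low-score cell lines (median split). Drugs with constant IC50
    are flagged degenerate and never candidates.
    """
    shared = [c for c in ic50.columns if c in set(cellline_scores.index)]
    if len(shared) < 10:
        raise ValueError("need >= 10 shared cell lines")
    scores = cellline_scores.loc[shared].to_numpy(dtype=float)
    high = scores > np.median(scores)
    rows = []
    for drug in ic50.index:
        vals = ic50.loc[drug, shared].to_numpy(dtype=float)
        ok = np.isfinite(vals)
        if ok.sum() < 10 or np.unique(vals[ok]).size < 2:
            rows.append(
                {"drug": drug, "rho": np.nan, "p": np.nan, "group_p": np.nan,
                 "degenerate": True}
            )
            continue
        rho, p = stats.spearmanr(scores[ok], vals[ok])
        hi, lo = vals[ok & high], vals[ok & ~high]
        group_p, _ = rank_sum_test(hi, lo) if len(hi) and len(lo) else (np.nan, np.nan)
        rows.append(
            {"drug": drug, "rho": float(rho), "p": float(p), "group_p": float(group_p),
             "degenerate": False}
        )
    table = pd.DataFrame(rows).set_index("drug")
    valid = ~table["degenerate"]
    q = np.full(len(table), np.nan)
    if valid.any():
        q[valid.to_numpy()] = bh_adjust(table.loc[valid, "p"].to_numpy())
    table["q"] = q
    table["candidate"] = valid & (table["rho"].abs() >= rho_min) & (table["q"] < q_max)
    return table
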