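"""Statsmodels-style entry point: :class:`IDICssModel` and :class:`IDICssResults`.

The model wraps the full pipeline — ICA decomposition, immune-component
selection, mutation-impact blending with lambda, consensus subgrouping,
subgroup differential expression, LASSO-Cox signature fitting and median
risk stratification — behind a single ``fit()`` call, with every stage's
intermediate result exposed on the results object.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from . import evaluate as ev
from .ica import ICADecomposition, fit_ica
from .io import CohortBundle, GeneExpressionMatrix, GeneSetCollection
from .profile import (
    DEFAULT_LAMBDA,
    IDICProfile,
    SubgroupAssignment,
    build_profile,
    consensus_cluster,
    driver_ic_association,
)
from .risk import GeneSignature, RiskScore, differential_genes, fit_lasso_cox, score_idicss
from .select import select_key_ics


@dataclass
class IDICssResults:
    """Fitted pipeline state: estimates, groupings and the trained signature."""

    model: "IDICssModel"
    decomposition: ICADecomposition
    relevance: pd.DataFrame
    key_ics: list[str]
    profile: IDICProfile
    subgroups: SubgroupAssignment
    driver_associations: pd.DataFrame
    de_table: pd.DataFrame
    signature: GeneSignature
    risk: RiskScore
    seed: int

    def predict_risk(self, expression: GeneExpressionMatrix) -> RiskScore:
        """Score a validation cohort with the trained signature and the
        frozen training-median threshold."""
        return score_idicss(expression, self.signature, threshold=self.risk.threshold)

    def evaluate(self, bundle: CohortBundle | None = None) -> ev.PerformanceReport:
        """C-index, log-rank, response AUC and classification metrics on the
        training cohort (default) or a validation bundle."""
        if bundle is None:
            bundle = self.model.bundle
            risk = self.risk
        else:
            risk = self.predict_risk(bundle.expression)
        clin = bundle.clinical.data.loc[risk.values.index]
        times = clin["os_time"].to_numpy(float)
        events = clin["os_event"].to_numpy(int)
        report = ev.PerformanceReport()
        report.c_index = ev.concordance_index(risk.values.to_numpy(), times, events)
        if events.sum() > 0 and risk.groups.nunique() > 1:
            comp = ev.km_logrank(times, events, risk.groups.to_numpy())
            report.logrank_p = comp.p_value
        if "response" in clin.columns:
            labels = ev.dichotomize_response(clin["response"])
            if labels.nunique() > 1:
                # lower iDICss predicts response; report the oriented AUC
                report.response_auc = ev.response_auc(-risk.values.to_numpy(), labels.to_numpy())
                report.classification = ev.classification_metrics(
                    risk.values.to_numpy(), labels.to_numpy(), risk.threshold
                )
        return report

    def summary(self) -> str:
        lines = [
            "iDICss model fit",
            "=" * 40,
            f"components fitted (k):       {self.decomposition.k}",
            f"key immune components:       {len(self.key_ics)} ({', '.join(self.key_ics)})",
            f"lambda (driver vs immune):   {self.profile.lambda_:.2f}",
            f"subgroups (PAC {self.subgroups.pac:.3f}):"
            f"  clusterA n={len(self.subgroups.samples_in('clusterA'))},"
            f" clusterB n={len(self.subgroups.samples_in('clusterB'))}",
            f"candidate DE genes:          {int(self.de_table['candidate'].sum())}",
            f"signature genes (nonzero):   {len(self.signature.genes)}",
            f"risk threshold (median):     {self.risk.threshold:.4f}",
        ]
        report = self.evaluate()
        lines.append(f"training C-index:            {report.c_index:.3f}")
        if report.logrank_p is not None:
            lines.append(f"log-rank p (high vs low):    {report.logrank_p:.3g}")
        if report.response_auc is not None:
            lines.append(f"response AUC (low=responder):{report.response_auc:.3f}")
        return "\n".join(lines)


@dataclass
class IDICssModel:
    """Configured but unfitted pipeline for one training cohort.

    Parameters mirror the pipeline stages: ``k`` independent components,
    selection thresholds, the mutation-blending ``lambda_`` (0.7 by
    default), consensus-clustering settings and the LASSO-Cox candidate
    thresholds.
    """

    bundle: CohortBundle
    immune_sets: GeneSetCollection
    ppi: nx.Graph
    driver_genes: list[str]
    k: int = 100
    lambda_: float = DEFAULT_LAMBDA
    z_threshold: float = 3.0
    q_max: float = 0.05
    p_max: float = 0.05
    n_perm: int = 999
    n_resample: int = 250
    de_q_max: float = 0.05
    de_fc_min: float = 1.0
    n_folds: int = 10
    min_mutated: int = 5

    def fit(self, seed: int = 0) -> IDICssResults:
        expr = self.bundle.expression
        decomp = fit_ica(expr, self.k, seed)
        relevance = select_key_ics(
            decomp,
            self.immune_sets,
            self.ppi,
            z_threshold=self.z_threshold,
            q_max=self.q_max,
            p_max=self.p_max,
            n_perm=self.n_perm,
            seed=seed,
        )
        key_ics = sorted(
            relevance.loc[relevance["selected"], "component"],
            key=lambda c: int(c[2:]),
        )
        if not key_ics:
            raise ValueError("no immune-relevant components selected")
        profile = build_profile(
            decomp,
            key_ics,
            self.bundle.mutations,
            set(self.driver_genes),
            set(self.immune_sets.union()),
            self.lambda_,
        )
        subgroups = consensus_cluster(
            profile,
            k=2,
            n_resample=self.n_resample,
            seed=seed,
            expression=expr,
            immune_sets=self.immune_sets,
        )
        if self.bundle.mutations is not None:
            assoc = driver_ic_association(
                decomp.W.loc[key_ics],
                self.bundle.mutations,
                self.driver_genes,
                self.min_mutated,
            )
        else:
            assoc = pd.DataFrame(
                columns=["gene", "component", "effect", "p", "direction", "n_mutated", "q"]
            )
        de = differential_genes(expr, subgroups, self.de_q_max, self.de_fc_min)
        candidates = list(de.index[de["candidate"]])
        signature = fit_lasso_cox(
            expr, self.bundle.clinical, candidates, n_folds=self.n_folds, seed=seed
        )
        risk = score_idicss(expr, signature)
        return IDICssResults(
            model=self,
            decomposition=decomp,
            relevance=relevance,
            key_ics=key_ics,
            profile=profile,
            subgroups=subgroups,
            driver_associations=assoc,
            de_table=de,
            signature=signature,
            risk=risk,
            seed=seed,
        )

    def lambda_sensitivity(
        self, lambdas: tuple[float, ...] = (0.5, 0.7, 0.8, 1.0), seed: int = 0
    ) -> pd.DataFrame:
        """Training C-index of the full pipeline across a lambda grid."""
        rows = []
        for lam in lambdas:
            model = IDICssModel(
                bundle=self.bundle,
                immune_sets=self.immune_sets,
                ppi=self.ppi,
                driver_genes=self.driver_genes,
                k=self.k,
                lambda_=lam,
                z_threshold=self.z_threshold,
                q_max=self.q_max,
                p_max=self.p_max,
                n_perm=self.n_perm,
                n_resample=self.n_resample,
                de_q_max=self.de_q_max,
                de_fc_min=self.de_fc_min,
                n_folds=self.n_folds,
            )
            try:
                res = model.fit(seed)
                rows.append(
                    {"lambda": lam, "c_index": res.evaluate().c_index,
                     "n_signature_genes": len(res.signature.genes)}
                )
            except Exception as exc:
                rows.append({"lambda": lam, "c_index": np.nan, "error": str(exc)})
        return pd.DataFrame(rows)
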