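"""Synthetic cohorts with planted structure for every pipeline stage.

The generator emulates the statistical skeleton of a bulk melanoma cohort
with matched mutation and outcome data:

* expression E = S0 @ W0 + noise, with heavy-tailed (Laplace) sparse gene
  loadings so the independent components are identifiable;
* a subset of components are "immune" components whose high-loading genes
  are drawn from designated immune gene sets (emitted as a GMT) and form
  planted cliques in an otherwise scale-free PPI network;
* two latent sample regimes (the future clusterA/clusterB) shift the immune
  components' mixing weights, giving the profile a recoverable two-cluster
  structure; the immune-hot regime also has lower planted risk;
* driver genes mutate with log-odds tied to a designated component's
  weights (the planted driver--component links);
* survival is exponential with log-hazard = sum of planted risk-gene
  coefficients times z-scored expression, censored independently;
* immunotherapy response is Bernoulli with logit decreasing in true risk.

Everything is reproducible from the config seed, and ``SimTruth`` records
all planted parameters for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .io import (
    ClinicalTable,
    CohortBundle,
    GeneExpressionMatrix,
    GeneSetCollection,
    MutationMatrix,
    write_gmt,
    write_matrix,
    write_ppi,
)
from .risk import GeneSignature


@dataclass
class SimConfig:
    """Planted-cohort parameters. Defaults are desk scale (< 1 min)."""

    n_genes: int = 2000
    n_samples: int = 300
    n_components: int = 10
    n_immune_components: int = 3
    immune_set_size: int = 60       # spike genes per immune component
    immune_set_extra: int = 20      # additional immune-set genes without loadings
    loading_sparsity: float = 0.03  # fraction of genes with spike loadings per component
    loading_scale: float = 3.0      # Laplace scale of spike loadings
    noise_sd: float = 0.5
    cluster_shift: float = 4.0      # immune-weight shift between the two regimes (hot vs cold)
    n_drivers: int = 20
    mutation_base_rate: float = 0.15
    background_mutation_rate: float = 0.08
    driver_effect: float = 1.5      # log-odds shift per SD of the linked component weight
    driver_immune_fraction: float = 0.5   # fraction of drivers linked to immune components
    immune_mutation_effect: float = 1.0   # log-odds shift of immune-gene mutations per SD
                                          # of the owning immune component's weight
    n_risk_genes: int = 10
    hazard_per_sd: float = float(np.log(2.0))  # log-hazard per SD (hazard ratio 2)
    risk_gene_cluster_shift: float = 1.2       # expression shift of risk genes in clusterB
    baseline_hazard: float = 1.0 / 1000.0      # events per day
    censoring_rate: float = 0.3
    response_slope: float = 1.5     # logit decrease per SD of true risk
    response_intercept: float = -0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_genes, self.n_samples, self.n_components, self.n_drivers) <= 0:
            raise ValueError("counts must be positive")
        if not 0 <= self.n_immune_components <= self.n_components:
            raise ValueError("n_immune_components must not exceed n_components")
        for rate in (self.mutation_base_rate, self.background_mutation_rate, self.censoring_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.n_immune_components * self.immune_set_size > self.n_genes // 2:
            raise ValueError("immune sets too large for the gene universe")


@dataclass
class SimTruth:
    """Planted parameters of one simulated cohort."""

    S: pd.DataFrame                      # genes x components
    W: pd.DataFrame                      # components x samples
    immune_components: list[str]
    immune_sets: GeneSetCollection
    driver_links: pd.DataFrame           # gene, component, sign, effect
    risk_genes: dict[str, float]         # gene -> log-hazard coefficient per SD
    risk: pd.Series                      # per-sample true log-hazard (z-scored)
    clusters: pd.Series                  # planted regime label per sample
    ppi: nx.Graph = field(repr=False, default=None)
    driver_genes: list[str] = field(default_factory=list)


def _component_ids(k: int) -> list[str]:
    return [f"source{i + 1}" for i in range(k)]


def simulate_cohort(
    config: SimConfig, truth: SimTruth | None = None
) -> tuple[CohortBundle, SimTruth]:
    """Generate one cohort plus its ground truth.

    When ``truth`` from a previous call is supplied, its planted structure
    (gene roles, loadings, driver links, risk coefficients, immune sets,
    PPI) is reused and only the sample-level draws — regimes, mixing
    weights, noise, mutations, survival, response — are regenerated from
    ``config.seed``, yielding an independent validation cohort from the same
    generative model.
    """
    rng = np.random.default_rng(config.seed)
    samples = [f"S{i + 1:04d}" for i in range(config.n_samples)]

    if truth is None:
        genes = [f"G{i + 1:05d}" for i in range(config.n_genes)]
        comp_ids = _component_ids(config.n_components)

        # --- gene roles ---------------------------------------------------
        perm = rng.permutation(config.n_genes)
        cursor = 0

        def take(n: int) -> list[str]:
            nonlocal cursor
            out = [genes[i] for i in perm[cursor : cursor + n]]
            cursor += n
            return out

        immune_spikes = [
            take(config.immune_set_size) for _ in range(config.n_immune_components)
        ]
        immune_extras = [
            take(config.immune_set_extra) for _ in range(config.n_immune_components)
        ]
        driver_genes = take(config.n_drivers)
        risk_genes = take(config.n_risk_genes)

        immune_sets = GeneSetCollection(
            {
                f"IMMUNE_SET_{i + 1}": frozenset(spk) | frozenset(ext)
                for i, (spk, ext) in enumerate(zip(immune_spikes, immune_extras))
            },
            provenance="synthetic immune signatures",
        )
        gene_pos = {g: i for i, g in enumerate(genes)}

        # --- loadings S0 (independent heavy-tailed columns) ---------------
        S0 = rng.laplace(0.0, 0.05, size=(config.n_genes, config.n_components))
        n_spike = max(5, int(round(config.loading_sparsity * config.n_genes)))
        for c in range(config.n_components):
            if c < config.n_immune_components:
                idx = [gene_pos[g] for g in immune_spikes[c]]
            else:
                pool = perm[cursor:]  # genes with no designated role
                idx = rng.choice(pool, size=n_spike, replace=False)
            signs = rng.choice([-1.0, 1.0], size=len(idx))
            S0[idx, c] += signs * rng.laplace(
                config.loading_scale, config.loading_scale / 3, size=len(idx)
            )

        # --- driver--component links --------------------------------------
        # drivers preferentially perturb the immune components: the premise
        # of the whole method is that driver mutations shape the TIME
        link_rows = []
        for g in driver_genes:
            if (
                config.n_immune_components > 0
                and rng.random() < config.driver_immune_fraction
            ):
                comp = int(rng.integers(0, config.n_immune_components))
            else:
                comp = int(rng.integers(0, config.n_components))
            sgn = float(rng.choice([-1.0, 1.0]))
            # the driver participates in the program it perturbs: give it a
            # loading on the linked component, signed like its mutation link,
            # so mutation impact projected through S carries real signal
            S0[gene_pos[g], comp] += sgn * rng.laplace(
                config.loading_scale, config.loading_scale / 3
            )
            link_rows.append(
                {
                    "gene": g,
                    "component": comp_ids[comp],
                    "sign": int(sgn),
                    "effect": config.driver_effect,
                }
            )
        driver_links = pd.DataFrame(link_rows)

        # --- risk-gene coefficients ---------------------------------------
        risk_signs = rng.choice([-1.0, 1.0], size=config.n_risk_genes)
        betas = {
            g: float(sgn * config.hazard_per_sd)
            for g, sgn in zip(risk_genes, risk_signs)
        }

        # --- PPI: scale-free backbone + cliques on immune spike genes -----
        ppi = nx.barabasi_albert_graph(
            config.n_genes, 2, seed=int(rng.integers(0, 2**31 - 1))
        )
        ppi = nx.relabel_nodes(ppi, {i: genes[i] for i in range(config.n_genes)})
        for spikes in immune_spikes:
            for i, a in enumerate(spikes):
                for b in spikes[i + 1 :]:
                    ppi.add_edge(a, b)
    else:
        genes = list(truth.S.index)
        comp_ids = list(truth.S.columns)
        if len(genes) != config.n_genes or len(comp_ids) != config.n_components:
            raise ValueError("config dimensions do not match the supplied truth")
        S0 = truth.S.to_numpy()
        immune_sets = truth.immune_sets
        driver_genes = list(truth.driver_genes)
        driver_links = truth.driver_links.copy()
        betas = dict(truth.risk_genes)
        risk_genes = list(betas)
        ppi = truth.ppi
        gene_pos = {g: i for i, g in enumerate(genes)}

    comp_index = {c: i for i, c in enumerate(comp_ids)}

    # --- sample regimes and mixing weights W0 -----------------------------
    regime = rng.random(config.n_samples) < 0.5  # True = immune-hot
    W0 = rng.normal(0.0, 1.0, size=(config.n_components, config.n_samples))
    for c in range(config.n_immune_components):
        W0[c] += np.where(regime, config.cluster_shift / 2, -config.cluster_shift / 2)

    # --- expression -------------------------------------------------------
    baseline = rng.normal(6.0, 1.5, size=(config.n_genes, 1))
    expr = baseline + S0 @ W0 + rng.normal(
        0.0, config.noise_sd, size=(config.n_genes, config.n_samples)
    )

    # risk genes: independent signal plus a regime shift (immune-hot = lower risk)
    for g in risk_genes:
        i = gene_pos[g]
        sgn = np.sign(betas[g])
        expr[i] = (
            baseline[i]
            + rng.normal(0.0, 1.0, size=config.n_samples)
            - sgn * config.risk_gene_cluster_shift * regime.astype(float)
        )

    expr_df = pd.DataFrame(expr, index=genes, columns=samples)
    expression = GeneExpressionMatrix(expr_df)

    # --- mutations --------------------------------------------------------
    def sigmoid(x: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-x))

    mutated_genes = driver_genes + sorted(immune_sets.union())
    mut = np.zeros((len(mutated_genes), config.n_samples), dtype=int)
    base_logit = np.log(config.mutation_base_rate / (1 - config.mutation_base_rate))
    bg_logit = np.log(
        config.background_mutation_rate / (1 - config.background_mutation_rate)
    )
    link_of = {row["gene"]: row for _, row in driver_links.iterrows()}
    for j, g in enumerate(driver_genes):
        link = link_of[g]
        comp = comp_index[link["component"]]
        w = (W0[comp] - W0[comp].mean()) / W0[comp].std()
        prob = sigmoid(base_logit + float(link["effect"]) * float(link["sign"]) * w)
        mut[j] = rng.random(config.n_samples) < prob
    # immune-set genes mutate with log-odds following their own program
    # activity, oriented by the gene's loading sign (active, highly
    # expressed programs accumulate detectable somatic mutations), so the
    # projected immune impact tracks the component weights
    set_names = list(immune_sets.sets)
    immune_comp_of: dict[str, int] = {}
    for i, name in enumerate(set_names[: config.n_immune_components]):
        for g in immune_sets.sets[name]:
            immune_comp_of.setdefault(g, i)
    for j in range(len(driver_genes), len(mutated_genes)):
        g = mutated_genes[j]
        comp = immune_comp_of.get(g)
        if comp is None or config.immune_mutation_effect == 0:
            prob = sigmoid(bg_logit)
        else:
            w = (W0[comp] - W0[comp].mean()) / W0[comp].std()
            orient = np.sign(S0[gene_pos[g], comp]) or 1.0
            prob = sigmoid(bg_logit + config.immune_mutation_effect * orient * w)
        mut[j] = rng.random(config.n_samples) < prob
    mutations = MutationMatrix(pd.DataFrame(mut, index=mutated_genes, columns=samples))

    # --- survival ---------------------------------------------------------
    z = expr_df.loc[risk_genes]
    z = (z.sub(z.mean(axis=1), axis=0)).div(z.std(axis=1, ddof=1), axis=0)
    log_hazard = np.zeros(config.n_samples)
    for g in risk_genes:
        log_hazard += betas[g] * z.loc[g].to_numpy()
    sd = log_hazard.std()
    risk_z = (log_hazard - log_hazard.mean()) / sd if sd > 0 else np.zeros_like(log_hazard)

    event_time = rng.exponential(1.0 / (config.baseline_hazard * np.exp(log_hazard)))
    if config.censoring_rate > 0:
        # independent exponential censoring calibrated to the target rate
        cens_hazard = config.baseline_hazard * config.censoring_rate / max(
            1 - config.censoring_rate, 1e-9
        )
        cens_time = rng.exponential(1.0 / cens_hazard, size=config.n_samples)
    else:
        cens_time = np.full(config.n_samples, np.inf)
    os_time = np.minimum(event_time, cens_time)
    os_event = (event_time <= cens_time).astype(int)

    # --- response ---------------------------------------------------------
    p_resp = sigmoid(config.response_intercept - config.response_slope * risk_z)
    responder = rng.random(config.n_samples) < p_resp
    response = np.where(responder, rng.choice(["CR", "PR"], size=config.n_samples),
                        rng.choice(["SD", "PD"], size=config.n_samples))

    clinical = ClinicalTable(
        pd.DataFrame(
            {
                "os_time": np.round(os_time, 2),
                "os_event": os_event,
                "pfs_time": np.round(os_time * rng.uniform(0.5, 1.0, config.n_samples), 2),
                "pfs_event": os_event,
                "response": response,
            },
            index=samples,
        )
    )

    bundle = CohortBundle(
        expression=expression,
        clinical=clinical,
        mutations=mutations,
        metadata={"origin": "idicss.simulate", "seed": str(config.seed)},
    )
    truth = SimTruth(
        S=pd.DataFrame(S0, index=genes, columns=comp_ids),
        W=pd.DataFrame(W0, index=comp_ids, columns=samples),
        immune_components=comp_ids[: config.n_immune_components],
        immune_sets=immune_sets,
        driver_links=driver_links,
        risk_genes=betas,
        risk=pd.Series(risk_z, index=samples, name="true_risk"),
        clusters=pd.Series(
            np.where(regime, "hot", "cold"), index=samples, name="regime"
        ),
        ppi=ppi,
        driver_genes=driver_genes,
    )
    return bundle, truth


def simulate_cellline_panel(
    signature: GeneSignature,
    n_lines: int = 60,
    n_drugs: int = 50,
    n_true_hits: int = 3,
    noise_sd: float = 0.3,
    seed: int = 0,
) -> tuple[GeneExpressionMatrix, pd.DataFrame, pd.DataFrame]:
    """Cell-line expression + drug IC50 panel with planted score-linked drugs.

    For "true hit" drugs the IC50 is a monotone (linear) function of the
    line's signature score plus noise; remaining drugs are independent.
    Returns (expression, IC50 drug x line matrix, truth table).
    """
    if not signature.genes:
        raise ValueError("signature must be non-empty")
    if n_true_hits > n_drugs:
        raise ValueError("n_true_hits cannot exceed n_drugs")
    rng = np.random.default_rng(seed)
    lines = [f"CL{i + 1:03d}" for i in range(n_lines)]
    sig_genes = signature.genes
    extra = [f"BG{i + 1:04d}" for i in range(200)]
    expr = pd.DataFrame(
        rng.normal(0.0, 1.0, size=(len(sig_genes) + len(extra), n_lines)),
        index=sig_genes + extra,
        columns=lines,
    )
    expression = GeneExpressionMatrix(expr)

    z = expr.loc[sig_genes]
    z = (z.sub(z.mean(axis=1), axis=0)).div(z.std(axis=1, ddof=1), axis=0)
    beta = np.array([signature.coefficients[g] for g in sig_genes])
    score = pd.Series(beta @ z.to_numpy(), index=lines)

    drugs = [f"DRUG{i + 1:03d}" for i in range(n_drugs)]
    hit_idx = rng.choice(n_drugs, size=n_true_hits, replace=False)
    ic50 = np.empty((n_drugs, n_lines))
    truth_rows = []
    score_z = (score - score.mean()) / (score.std() if score.std() > 0 else 1.0)
    for d in range(n_drugs):
        if d in hit_idx:
            slope = float(rng.choice([-1.0, 1.0]))
            ic50[d] = 5.0 + slope * score_z.to_numpy() + (
                rng.normal(0.0, noise_sd, n_lines) if noise_sd > 0 else 0.0
            )
            truth_rows.append({"drug": drugs[d], "true_hit": True, "slope": slope})
        else:
            ic50[d] = 5.0 + rng.normal(0.0, 1.0, n_lines)
            truth_rows.append({"drug": drugs[d], "true_hit": False, "slope": 0.0})
    return (
        expression,
        pd.DataFrame(ic50, index=drugs, columns=lines),
        pd.DataFrame(truth_rows).set_index("drug"),
    )


def write_cohort(bundle: CohortBundle, truth: SimTruth, outdir: str | Path) -> None:
    """Emit the cohort as the plain-text formats the loaders read."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_matrix(bundle.expression.data, outdir / "expression.tsv", provenance="idicss simulate")
    if bundle.mutations is not None:
        write_matrix(bundle.mutations.data, outdir / "mutations.tsv", provenance="idicss simulate")
    write_matrix(bundle.clinical.data, outdir / "clinical.tsv", provenance="idicss simulate")
    write_gmt(truth.immune_sets, outdir / "immune.gmt")
    write_ppi(truth.ppi, outdir / "ppi.tsv")
    with open(outdir / "drivers.txt", "w") as fh:
        fh.write("\n".join(truth.driver_genes) + "\n")
    truth.clusters.to_frame().to_csv(outdir / "true_clusters.tsv", sep="\t")
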