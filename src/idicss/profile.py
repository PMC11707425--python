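"""The immune-driver independent component (iDIC) profile.

Mutation impacts are projected onto the key components through the gene
loadings: for a gene set G, ``impact(c, s) = sum_{g in G, mut(g,s)=1} S[g, c]``,
row z-scored across samples. Driver-gene and immune-gene impacts are then
blended into the component weights with a single parameter lambda in [0, 1]:

    iDIC(c, s) = W~(c, s) + lambda * D(c, s) + (1 - lambda) * I(c, s)

where W~ are the z-scored mixing weights of the key components, D the driver
impact and I the immune impact. lambda = 0.7 by default, i.e. driver
mutations carry 70% of the mutation influence. Unsupervised consensus
clustering of the profile yields the two iDIC subgroups (clusterA has the
colder immune microenvironment by convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans

from .ica import ICADecomposition
from .io import GeneExpressionMatrix, GeneSetCollection, MutationMatrix
from .select import bh_adjust

DEFAULT_LAMBDA = 0.7
DEFAULT_MIN_MUTATED = 5
DEFAULT_N_RESAMPLE = 250
DEFAULT_SUBSAMPLE_FRAC = 0.8
FORMULA_VERSION = "additive-v1"


@dataclass
class IDICProfile:
    """Key-component x sample iDIC matrix with its blending provenance."""

    data: pd.DataFrame
    lambda_: float
    driver_label: str = "drivers"
    immune_label: str = "immune"
    formula: str = FORMULA_VERSION

    def __post_init__(self) -> None:
        if not np.isfinite(self.data.to_numpy()).all():
            raise ValueError("iDIC profile contains non-finite entries")

    @property
    def components(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class SubgroupAssignment:
    """Consensus-clustering subgroups with a PAC quality score."""

    labels: pd.Series  # sample -> "clusterA" / "clusterB" / ...
    k: int
    pac: float
    consensus: pd.DataFrame | None = field(default=None, repr=False)

    def samples_in(self, label: str) -> list[str]:
        return list(self.labels.index[self.labels == label])


def zscore_rows(data: pd.DataFrame) -> pd.DataFrame:
    """Row-wise z-score; zero-variance rows map to 0."""
    vals = data.to_numpy(dtype=float)
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=1, keepdims=True)
    out = np.divide(vals - mean, sd, out=np.zeros_like(vals), where=sd > 0)
    return pd.DataFrame(out, index=data.index, columns=data.columns)


def rank_sum_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum p and rank-biserial effect size.

    Exact null distribution when both groups have < 10 observations and no
    ties; otherwise the normal approximation with tie correction.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (len(x) < 10 and len(y) < 10 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    effect = 2.0 * res.statistic / (len(x) * len(y)) - 1.0
    return float(res.pvalue), float(effect)


def driver_ic_association(
    W: pd.DataFrame,
    mutations: MutationMatrix,
    genes: list[str],
    min_mutated: int = DEFAULT_MIN_MUTATED,
) -> pd.DataFrame:
    """Rank-sum association between gene mutation status and component weights.

    One row per tested (gene, component): rank-biserial effect, two-sided
    rank-sum p, BH q over all tests, and the direction (sign of the median
    weight difference, mutated minus wild-type). Genes mutated in fewer than
    ``min_mutated`` samples are skipped.
    """
    samples = list(W.columns)
    mut = mutations.data.reindex(columns=samples, fill_value=0)
    rows = []
    for gene in genes:
        if gene not in mut.index:
            continue
        carrier = mut.loc[gene].to_numpy() == 1
        if carrier.sum() < min_mutated or (~carrier).sum() < 1:
            continue
        for comp in W.index:
            w = W.loc[comp].to_numpy(dtype=float)
            p, effect = rank_sum_test(w[carrier], w[~carrier])
            med_diff = float(np.median(w[carrier]) - np.median(w[~carrier]))
            rows.append(
                {
                    "gene": gene,
                    "component": comp,
                    "effect": effect,
                    "p": p,
                    "direction": "+" if med_diff >= 0 else "-",
                    "n_mutated": int(carrier.sum()),
                }
            )
    table = pd.DataFrame(
        rows, columns=["gene", "component", "effect", "p", "direction", "n_mutated"]
    )
    if len(table):
        table["q"] = bh_adjust(table["p"].to_numpy())
    else:
        table["q"] = pd.Series(dtype=float)
    return table


def mutation_impact(
    S: pd.DataFrame,
    mutations: MutationMatrix,
    gene_set: set[str],
    key_ics: list[str],
    samples: list[str] | None = None,
) -> pd.DataFrame:
    """Project mutations in ``gene_set`` onto the key components.

    impact(c, s) = sum over mutated set genes g of S[g, c]; rows are then
    z-scored across samples (zero-variance rows -> 0).
    """
    genes = sorted(set(gene_set) & set(S.index) & set(mutations.genes))
    if not set(gene_set) & set(S.index):
        raise ValueError("gene_set shares no genes with the loading matrix")
    if samples is None:
        samples = list(mutations.samples)
    mut = mutations.data.reindex(index=genes, columns=samples, fill_value=0)
    loadings = S.loc[genes, key_ics]  # genes x key ICs
    raw = loadings.to_numpy().T @ mut.to_numpy()  # key ICs x samples
    return zscore_rows(pd.DataFrame(raw, index=key_ics, columns=samples))


def blend_idic(
    W_z: pd.DataFrame,
    driver_impact: pd.DataFrame,
    immune_impact: pd.DataFrame,
    lambda_: float = DEFAULT_LAMBDA,
) -> IDICProfile:
    """Blend z-scored key-component weights with the two mutation impacts."""
    if not 0.0 <= lambda_ <= 1.0:
        raise ValueError("lambda must lie in [0, 1]")
    for other, name in ((driver_impact, "driver"), (immune_impact, "immune")):
        if other.shape != W_z.shape or list(other.index) != list(W_z.index) or list(
            other.columns
        ) != list(W_z.columns):
            raise ValueError(f"{name} impact matrix not aligned with the weights")
    data = W_z + lambda_ * driver_impact + (1.0 - lambda_) * immune_impact
    return IDICProfile(data=data, lambda_=lambda_)


def signature_score(expr: GeneExpressionMatrix, gene_set: set[str]) -> pd.Series:
    """Mean of gene-wise z-scored expression over the set genes, per sample."""
    genes = sorted(set(gene_set) & set(expr.genes))
    if not genes:
        raise ValueError("gene set shares no genes with the expression matrix")
    z = zscore_rows(expr.data.loc[genes])
    return z.mean(axis=0)


def consensus_cluster(
    profile: IDICProfile,
    k: int = 2,
    n_resample: int = DEFAULT_N_RESAMPLE,
    subsample_frac: float = DEFAULT_SUBSAMPLE_FRAC,
    seed: int = 0,
    *,
    expression: GeneExpressionMatrix | None = None,
    immune_sets: GeneSetCollection | None = None,
    keep_consensus: bool = False,
) -> SubgroupAssignment:
    """Resampling-based consensus clustering of the iDIC profile.

    ``n_resample`` k-means runs on random ``subsample_frac`` sample subsets;
    the consensus matrix is the co-assignment frequency among co-sampled
    pairs; final labels come from an average-linkage hierarchical cut of
    (1 - consensus) at k. When expression and immune sets are supplied,
    "clusterA" is the cluster with the lower mean immune signature score;
    otherwise clusters are labelled largest-first. PAC (proportion of
    ambiguous clustering, consensus entries in (0.1, 0.9)) is reported.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    X = profile.data.to_numpy().T  # samples x components
    n = X.shape[0]
    if n < 2 * k:
        raise ValueError("need at least 2*k samples")
    rng = np.random.default_rng(seed)
    size = max(k, int(round(subsample_frac * n)))
    together = np.zeros((n, n))
    sampled = np.zeros((n, n))
    for _ in range(n_resample):
        idx = rng.choice(n, size=size, replace=False)
        km = KMeans(n_clusters=k, n_init=5, random_state=int(rng.integers(0, 2**31 - 1)))
        labels = km.fit_predict(X[idx])
        same = labels[:, None] == labels[None, :]
        sampled[np.ix_(idx, idx)] += 1
        together[np.ix_(idx, idx)] += same
    with np.errstate(invalid="ignore"):
        consensus = np.where(sampled > 0, together / np.maximum(sampled, 1), 0.0)
    np.fill_diagonal(consensus, 1.0)
    consensus = (consensus + consensus.T) / 2

    dist = squareform(1.0 - consensus, checks=False)
    tree = linkage(dist, method="average")
    raw = fcluster(tree, t=k, criterion="maxclust")
    if len(np.unique(raw)) < k:
        # degenerate consensus: fall back to one deterministic k-means
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        raw = km.fit_predict(X) + 1

    off = consensus[~np.eye(n, dtype=bool)]
    pac = float(((off > 0.1) & (off < 0.9)).mean())

    samples = profile.samples
    clusters = {c: [samples[i] for i in np.flatnonzero(raw == c)] for c in np.unique(raw)}
    letters = [chr(ord("A") + i) for i in range(k)]
    if expression is not None and immune_sets is not None:
        score = signature_score(expression, immune_sets.union())
        order = sorted(clusters, key=lambda c: score[clusters[c]].mean())
    else:
        order = sorted(clusters, key=lambda c: (-len(clusters[c]), c))
    name_of = {c: f"cluster{letters[i]}" for i, c in enumerate(order)}
    labels = pd.Series(
        {s: name_of[c] for c, members in clusters.items() for s in members},
        name="subgroup",
    ).loc[samples]
    return SubgroupAssignment(
        labels=labels,
        k=k,
        pac=pac,
        consensus=pd.DataFrame(consensus, index=samples, columns=samples)
        if keep_consensus
        else None,
    )


def build_profile(
    decomp: ICADecomposition,
    key_ics: list[str],
    mutations: MutationMatrix | None,
    driver_genes: set[str],
    immune_genes: set[str],
    lambda_: float = DEFAULT_LAMBDA,
) -> IDICProfile:
    """Convenience wrapper: z-score key-component weights, compute both
    mutation impacts (zero when mutations are absent or disjoint), and blend."""
    W_z = zscore_rows(decomp.W.loc[key_ics])
    zero = pd.DataFrame(0.0, index=key_ics, columns=W_z.columns)

    def impact(gene_set: set[str]) -> pd.DataFrame:
        if mutations is None or not set(gene_set) & set(decomp.genes):
            return zero.copy()
        return mutation_impact(decomp.S, mutations, gene_set, key_ics, list(W_z.columns))

    return blend_idic(W_z, impact(driver_genes), impact(immune_genes), lambda_)
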