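"""Independent component analysis of an expression cohort.

The expression matrix E (genes x samples) is decomposed as E_centered ~ S @ W
where S (genes x k) holds the gene loadings of each independent component and
W (k x samples) the per-sample mixing weights. Genes are the observation
dimension, so components are sources that are statistically independent
across genes; heavy-tailed (super-Gaussian) loading distributions make the
decomposition identifiable up to permutation and sign.

Conventions fixed here so results are reproducible:

* each column of S has unit sample variance (ddof=1), compensated in W;
* each column of S is flipped so its skewness is non-negative;
* components are labelled ``IC1..ICk``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import FastICA

from .io import GeneExpressionMatrix

DEFAULT_K = 100
DEFAULT_TOL = 1e-6
DEFAULT_MAX_ITER = 1000


@dataclass
class ICADecomposition:
    """Result of one ICA fit.

    ``S`` is genes x k, ``W`` is k x samples; ``centered`` holds the
    double-centered expression matrix the factorization approximates.
    """

    S: pd.DataFrame
    W: pd.DataFrame
    k: int
    seed: int
    n_iter: int
    converged: bool
    centered: pd.DataFrame | None = None

    @property
    def components(self) -> list[str]:
        return list(self.S.columns)

    @property
    def genes(self) -> list[str]:
        return list(self.S.index)

    @property
    def samples(self) -> list[str]:
        return list(self.W.columns)

    def reconstruction_error(self) -> float:
        """Relative Frobenius reconstruction error of the centered matrix."""
        if self.centered is None:
            raise ValueError("centered matrix not retained")
        E = self.centered.to_numpy()
        resid = E - self.S.to_numpy() @ self.W.to_numpy()
        return float(np.linalg.norm(resid) / np.linalg.norm(E))


@dataclass
class StabilityReport:
    """Per-component multi-restart stability (mean matched |r| across runs)."""

    stability: pd.Series
    n_runs: int
    matching: str = "greedy max |Pearson r| on S columns"

    def __post_init__(self) -> None:
        vals = self.stability.to_numpy()
        if ((vals < -1e-9) | (vals > 1 + 1e-9)).any():
            raise ValueError("stability indices must lie in [0, 1]")


def _double_center(values: np.ndarray) -> np.ndarray:
    values = values - values.mean(axis=1, keepdims=True)
    return values - values.mean(axis=0, keepdims=True)


def fit_ica(
    expr: GeneExpressionMatrix,
    k: int,
    seed: int,
    *,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> ICADecomposition:
    """FastICA (parallel extraction, logcosh contrast) with fixed conventions.

    Deterministic given ``(expr, k, seed)``. Non-convergence within
    ``max_iter`` is recorded on the result, not raised.
    """
    values = expr.values
    if np.isnan(values).any():
        raise ValueError("expression contains NaN")
    n_genes, n_samples = values.shape
    if not 1 <= k <= min(n_genes, n_samples):
        raise ValueError(f"k={k} must be in [1, min(genes, samples)={min(n_genes, n_samples)}]")

    centered = _double_center(values)
    ica = FastICA(
        n_components=k,
        algorithm="parallel",
        fun="logcosh",
        whiten="unit-variance",
        tol=tol,
        max_iter=max_iter,
        random_state=seed,
    )
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sources = ica.fit_transform(centered)  # genes x k
    mixing = ica.mixing_  # samples x k
    S = np.asarray(sources, dtype=float)
    W = np.asarray(mixing, dtype=float).T  # k x samples

    # unit sample variance per loading column, compensated in W
    scale = S.std(axis=0, ddof=1)
    scale[scale == 0] = 1.0
    S = S / scale
    W = W * scale[:, None]

    # sign convention: non-negative loading skewness
    skew = stats.skew(S, axis=0)
    flip = np.where(skew < 0, -1.0, 1.0)
    S = S * flip
    W = W * flip[:, None]

    ids = [f"IC{i + 1}" for i in range(k)]
    return ICADecomposition(
        S=pd.DataFrame(S, index=expr.genes, columns=ids),
        W=pd.DataFrame(W, index=ids, columns=expr.samples),
        k=k,
        seed=seed,
        n_iter=int(ica.n_iter_),
        converged=bool(ica.n_iter_ < max_iter),
        centered=pd.DataFrame(centered, index=expr.genes, columns=expr.samples),
    )


def _greedy_match(ref: np.ndarray, other: np.ndarray) -> np.ndarray:
    """Greedy 1:1 matching by maximal |Pearson r| between columns.

    Returns, for each reference column, the |r| of its matched partner.
    """
    corr = np.abs(np.corrcoef(ref.T, other.T)[: ref.shape[1], ref.shape[1]:])
    matched_r = np.zeros(ref.shape[1])
    corr = corr.copy()
    for _ in range(min(corr.shape)):
        i, j = np.unravel_index(np.nanargmax(corr), corr.shape)
        matched_r[i] = corr[i, j]
        corr[i, :] = -np.inf
        corr[:, j] = -np.inf
    return matched_r


def stability_select(
    expr: GeneExpressionMatrix,
    k: int,
    n_runs: int,
    seed: int,
    *,
    seeds: list[int] | None = None,
    **fit_kwargs,
) -> StabilityReport:
    """Multi-restart stability: refit with derived seeds, greedily match
    components of the reference run to each restart by |Pearson r| of the S
    columns, and average the matched correlations."""
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    if seeds is None:
        rng = np.random.default_rng(seed)
        seeds = rng.integers(0, 2**31 - 1, size=n_runs)
    elif len(seeds) != n_runs:
        raise ValueError("len(seeds) must equal n_runs")
    ref = fit_ica(expr, k, int(seeds[0]), **fit_kwargs)
    matched = np.zeros((n_runs - 1, k))
    for r in range(1, n_runs):
        run = fit_ica(expr, k, int(seeds[r]), **fit_kwargs)
        matched[r - 1] = _greedy_match(ref.S.to_numpy(), run.S.to_numpy())
    index = np.clip(matched.mean(axis=0), 0.0, 1.0)
    return StabilityReport(
        stability=pd.Series(index, index=ref.components, name="stability"),
        n_runs=n_runs,
    )


def top_genes(
    decomp: ICADecomposition, component: str, z_threshold: float = 3.0
) -> dict[str, int]:
    """Genes whose loading z-score within the component exceeds ``z_threshold``
    in absolute value; returns gene -> sign(loading)."""
    if component not in decomp.S.columns:
        raise KeyError(f"unknown component {component!r}")
    if z_threshold <= 0:
        raise ValueError("z_threshold must be positive")
    col = decomp.S[component]
    z = (col - col.mean()) / col.std(ddof=1)
    hits = z[np.abs(z) > z_threshold]
    return {gene: (1 if val > 0 else -1) for gene, val in hits.items()}
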