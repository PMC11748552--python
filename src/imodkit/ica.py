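"""Robust independent component analysis of a centered compendium.

Decomposes ``X`` (genes x samples, centered log units) as ``X = S A``:
FastICA is run from many random initializations at a given dimension, the
pooled gene-weight components are clustered under the 1 - |Pearson r|
distance, and only clusters recurring in enough runs survive. Each robust
component is represented by its centrotype (the member minimizing summed
distance to its cluster), sign-oriented so the largest-magnitude gene weight
is positive, with activities recomputed by least squares against ``X`` so
that ``S A`` is exactly the projection of ``X`` onto the component span.

Dimension selection follows the OptICA idea: scan a grid of dimensions and
track how many reproducible components are *not* single-gene (one gene
dominating the squared weight); the selected dimension is the smallest one
reaching the plateau of that count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN

from .exceptions import ConfigurationError, DimensionError
from .preprocess import ExpressionMatrix

_TOL = 1e-6
_MAX_ITER = 1000


@dataclass
class ComponentSet:
    """Robust decomposition ``X ~ S A`` with run provenance.

    ``S`` is genes x d with unit-norm columns; ``A`` is d x samples.
    ``reproducibility[c]`` is the fraction of runs whose pool contributed to
    component c's cluster.
    """

    S: pd.DataFrame
    A: pd.DataFrame
    dim_requested: int
    run_seeds: list[int] = field(default_factory=list)
    reproducibility: list[float] = field(default_factory=list)
    converged: bool = True

    @property
    def n_components(self) -> int:
        return self.S.shape[1]

    def explained_variance_total(self, x: ExpressionMatrix) -> float:
        """1 - ||X - S A||_F^2 / ||X||_F^2 over the training matrix."""
        X = x.data.loc[self.S.index].to_numpy()
        resid = X - self.S.to_numpy() @ self.A.to_numpy()
        total = float(np.linalg.norm(X) ** 2)
        return 1.0 - float(np.linalg.norm(resid) ** 2) / total


def _logcosh(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    g = np.tanh(u)
    g_prime = 1.0 - g**2
    return g, g_prime


def _sym_decorrelate(W: np.ndarray) -> np.ndarray:
    # W <- (W W^T)^(-1/2) W via eigendecomposition
    s, u = np.linalg.eigh(W @ W.T)
    s = np.clip(s, 1e-12, None)
    return (u * (1.0 / np.sqrt(s))) @ u.T @ W


def _orient(S: np.ndarray) -> np.ndarray:
    """Flip component signs so the largest-magnitude gene weight is positive."""
    flips = np.sign(S[np.abs(S).argmax(axis=0), np.arange(S.shape[1])])
    flips[flips == 0] = 1.0
    return S * flips


def ica_once(
    x: ExpressionMatrix, dim: int, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame, bool]:
    """One FastICA run at a fixed dimension.

    Whitens to ``dim`` dimensions by SVD, then runs the symmetric fixed-point
    iteration with the log-cosh contrast (tolerance 1e-6, at most 1000
    iterations). Returns unit-norm gene-weight columns ``S``, activities
    ``A`` solving the least-squares fit (so ``S A`` is the rank-``dim``
    approximation of ``x``), and a convergence flag.
    """
    if dim < 2:
        raise DimensionError("ica dimension must be at least 2")
    X = x.values
    n_genes = X.shape[0]
    U, sv, Vt = np.linalg.svd(X, full_matrices=False)
    rank = int((sv > sv[0] * 1e-10).sum())
    if dim > rank:
        raise DimensionError(f"dim {dim} exceeds matrix rank {rank}")
    # whitened observations: each gene is a dim-vector with identity covariance
    Z = (np.sqrt(n_genes) * U[:, :dim]).T  # dim x genes

    rng = np.random.default_rng(seed)
    W = _sym_decorrelate(rng.standard_normal((dim, dim)))
    converged = False
    for _ in range(_MAX_ITER):
        g, g_prime = _logcosh(W @ Z)
        W_new = (g @ Z.T) / n_genes - g_prime.mean(axis=1)[:, None] * W
        W_new = _sym_decorrelate(W_new)
        delta = float(np.max(np.abs(np.abs(np.einsum("ij,ij->i", W_new, W)) - 1)))
        W = W_new
        if delta < _TOL:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"FastICA did not converge in {_MAX_ITER} iterations (dim={dim}, "
            f"seed={seed}); returning partial result",
            stacklevel=2,
        )
    S = (W @ Z).T  # genes x dim
    S /= np.linalg.norm(S, axis=0, keepdims=True)
    S = _orient(S)
    A, *_ = np.linalg.lstsq(S, X, rcond=None)
    ids = [f"IC_{i + 1}" for i in range(dim)]
    S_df = pd.DataFrame(S, index=x.gene_ids, columns=ids)
    A_df = pd.DataFrame(A, index=ids, columns=x.sample_ids)
    return S_df, A_df, converged


def _abs_corr_distance(components: np.ndarray) -> np.ndarray:
    """Pairwise 1 - |Pearson r| between component columns."""
    r = np.corrcoef(components.T)
    return np.clip(1.0 - np.abs(r), 0.0, None)


def robust_components(
    x: ExpressionMatrix,
    dim: int,
    n_runs: int = 10,
    seeds: list[int] | None = None,
    cluster_radius: float = 0.3,
    min_fraction: float = 0.5,
    resample: bool = True,
) -> ComponentSet:
    """Cluster components pooled over FastICA runs; keep the recurrent ones.

    By default each run sees a bootstrap resample of the sample columns in
    addition to a fresh random initialization; spurious components driven by
    finite-sample fluctuations then move between runs while genuine sources
    recur. ``resample=False`` reruns on the fixed matrix (initialization is
    the only run-to-run difference), which keeps the retained components
    exactly inside the whitened subspace of ``x``. Components within
    ``cluster_radius`` in 1 - |Pearson r| distance are grouped by DBSCAN
    (min_samples = ceil(min_fraction * n_runs)); a cluster survives when it
    contains components from at least ``min_fraction`` of the runs. The
    representative is the sign-aligned cluster mean anchored at the
    centrotype (the member minimizing summed distance to the cluster);
    averaging across runs cancels run-specific estimation noise in the gene
    weights.
    """
    if n_runs < 1:
        raise ConfigurationError("n_runs must be >= 1")
    if seeds is None:
        seeds = list(range(n_runs))
    if len(seeds) != n_runs:
        raise ConfigurationError("need exactly one seed per run")

    n_samples = x.shape[1]
    pool: list[np.ndarray] = []
    run_of: list[int] = []
    all_converged = True
    for run, seed in enumerate(seeds):
        if resample:
            rng = np.random.default_rng(np.random.SeedSequence([int(seed), 11]))
            idx = rng.integers(0, n_samples, n_samples)
            boot = x.data.iloc[:, idx]
            boot = boot.set_axis([f"b{i}" for i in range(n_samples)], axis=1)
            x_run = ExpressionMatrix(boot, space=x.space)
        else:
            x_run = x
        S, _, conv = ica_once(x_run, dim, seed=seed)
        all_converged &= conv
        for c in range(S.shape[1]):
            pool.append(S.iloc[:, c].to_numpy())
            run_of.append(run)
    P = np.column_stack(pool)
    D = _abs_corr_distance(P)

    min_samples = max(1, int(np.ceil(min_fraction * n_runs)))
    labels = DBSCAN(
        eps=cluster_radius, min_samples=min_samples, metric="precomputed"
    ).fit_predict(D)

    reps: list[np.ndarray] = []
    repro: list[float] = []
    run_arr = np.asarray(run_of)
    for lab in sorted(set(labels) - {-1}):
        members = np.flatnonzero(labels == lab)
        frac = len(set(run_arr[members])) / n_runs
        if frac < min_fraction:
            continue
        sub = D[np.ix_(members, members)]
        centrotype = members[int(sub.sum(axis=1).argmin())]
        anchor = P[:, centrotype]
        signs = np.sign(P[:, members].T @ anchor)
        signs[signs == 0] = 1.0
        rep = (P[:, members] * signs).mean(axis=1)
        rep /= np.linalg.norm(rep)
        reps.append(rep)
        repro.append(frac)
    if not reps:
        warnings.warn("no robust component clusters found", stacklevel=2)
        S_df = pd.DataFrame(index=x.gene_ids)
        A_df = pd.DataFrame(columns=x.sample_ids)
        return ComponentSet(S_df, A_df, dim, list(seeds), [])

    # order components by reproducibility then by pooled order for determinism
    order = sorted(range(len(reps)), key=lambda i: (-repro[i], i))
    S = _orient(np.column_stack([reps[i] for i in order]))
    repro = [repro[i] for i in order]
    A, *_ = np.linalg.lstsq(S, x.values, rcond=None)
    ids = [f"IC_{i + 1}" for i in range(S.shape[1])]
    return ComponentSet(
        S=pd.DataFrame(S, index=x.gene_ids, columns=ids),
        A=pd.DataFrame(A, index=ids, columns=x.sample_ids),
        dim_requested=dim,
        run_seeds=list(seeds),
        reproducibility=repro,
        converged=all_converged,
    )


def is_single_gene(weights: np.ndarray, fraction: float = 0.5) -> bool:
    """True when one gene carries more than ``fraction`` of the squared norm."""
    w2 = np.square(weights)
    return bool(w2.max() > fraction * w2.sum())


def optica(
    x: ExpressionMatrix,
    dim_grid: list[int],
    n_runs: int = 10,
    seeds: list[int] | None = None,
    cluster_radius: float = 0.3,
    min_fraction: float = 0.5,
    single_gene_fraction: float = 0.5,
    plateau_tolerance: int = 0,
    resample: bool = True,
) -> tuple[int, pd.DataFrame]:
    """Select the ICA dimension from a grid by the non-single-gene plateau.

    For each grid dimension the robust decomposition is computed and its
    components classified as single-gene or not. The optimum is the smallest
    dimension whose non-single-gene count is within ``plateau_tolerance`` of
    the maximum over the grid — past the true dimensionality, extra
    components are either irreproducible or single-gene, so the count
    plateaus. Returns the chosen dimension and a per-dimension diagnostics
    table (robust / single-gene / non-single-gene counts).
    """
    if not dim_grid:
        raise ConfigurationError("empty dimension grid")
    X = x.values
    sv = np.linalg.svd(X, compute_uv=False)
    rank = int((sv > sv[0] * 1e-10).sum())
    for d in dim_grid:
        if d > rank:
            raise ConfigurationError(f"grid dimension {d} exceeds rank {rank}")

    rows = []
    results: dict[int, ComponentSet] = {}
    for d in sorted(dim_grid):
        if seeds is None:
            run_seeds = list(range(n_runs))
        else:
            run_seeds = list(seeds)
        cs = robust_components(
            x, d, n_runs=n_runs, seeds=run_seeds,
            cluster_radius=cluster_radius, min_fraction=min_fraction,
            resample=resample,
        )
        results[d] = cs
        n_single = sum(
            is_single_gene(cs.S.iloc[:, c].to_numpy(), single_gene_fraction)
            for c in range(cs.n_components)
        )
        rows.append(
            {
                "dim": d,
                "n_robust": cs.n_components,
                "n_single_gene": n_single,
                "n_non_single_gene": cs.n_components - n_single,
            }
        )
    diag = pd.DataFrame(rows).set_index("dim")
    best = int(diag["n_non_single_gene"].max())
    candidates = diag.index[diag["n_non_single_gene"] >= best - plateau_tolerance]
    optimal = int(candidates.min())
    return optimal, diag
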