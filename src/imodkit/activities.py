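"""iModulon activity inference and downstream analytics.

New samples are projected onto a fixed gene-weight matrix by least squares,
activities are re-expressed relative to a reference sample (a subtraction,
since activities live on a log-fold-change-like scale and cross zero),
pairs of samples are compared with a fixed up/down threshold, activity
trajectories are correlated, and iModulons are hierarchically clustered by
their activity profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .exceptions import (
    ConfigurationError,
    IdentifierError,
    UndefinedCorrelationError,
)
from .preprocess import ExpressionMatrix

DIFF_THRESHOLD = 5.0


@dataclass
class ActivityTable:
    """iModulons x samples activities with a normalization tag."""

    data: pd.DataFrame
    normalization: Literal["raw", "reference_relative"] = "raw"

    @property
    def imodulon_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class DifferentialCall:
    imodulon_id: str
    condition_pair: tuple[str, str]
    delta_activity: float
    call: Literal["U", "D", "-"]


def infer_activities(
    M: pd.DataFrame, x_new: ExpressionMatrix
) -> ActivityTable:
    """Least-squares activities of a fixed structure in new samples.

    Gene universes are intersected and aligned first; per sample the
    activity vector minimizes ||x - M a||_2 (minimum-norm solution, with a
    warning, when M is rank-deficient). Residuals are orthogonal to every
    column of M.
    """
    shared = [g for g in M.index if g in set(x_new.gene_ids)]
    if len(shared) < M.shape[1]:
        raise ValueError(
            f"only {len(shared)} shared genes for {M.shape[1]} components"
        )
    Ms = M.loc[shared].to_numpy(dtype=float)
    X = x_new.data.loc[shared].to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(Ms)
    if rank < Ms.shape[1]:
        warnings.warn(
            "rank-deficient gene-weight matrix: returning the minimum-norm "
            "activity solution",
            stacklevel=2,
        )
    A, *_ = np.linalg.lstsq(Ms, X, rcond=None)
    return ActivityTable(
        pd.DataFrame(A, index=list(M.columns), columns=x_new.sample_ids),
        normalization="raw",
    )


def normalize_to_reference(
    a: ActivityTable, reference_sample_id: str
) -> ActivityTable:
    """Subtract the reference sample's activity from every sample."""
    if reference_sample_id not in a.data.columns:
        raise IdentifierError(f"unknown sample {reference_sample_id!r}")
    shifted = a.data.sub(a.data[reference_sample_id], axis=0)
    return ActivityTable(shifted, normalization="reference_relative")


def average_replicates(a: ActivityTable, metadata: pd.DataFrame) -> ActivityTable:
    """Average activity columns over replicates of each (condition, time).

    Output columns are named ``{condition}_t{time}``; used upstream of
    differential calls so a comparison is between condition means.
    """
    meta = metadata.copy()
    if "sample_id" in meta.columns:
        meta = meta.set_index("sample_id")
    meta = meta.loc[[s for s in a.sample_ids if s in meta.index]]
    cols = {}
    for (cond, t), group in meta.groupby(["condition", "time_h"], sort=True):
        cols[f"{cond}_t{t:g}"] = a.data[list(group.index)].mean(axis=1)
    return ActivityTable(pd.DataFrame(cols), normalization=a.normalization)


def differential_calls(
    a: ActivityTable,
    sample_a: str,
    sample_b: str,
    threshold: float = DIFF_THRESHOLD,
) -> list[DifferentialCall]:
    """Up/down/no-change calls between two samples at a fixed threshold.

    delta = activity(sample_b) - activity(sample_a); the call is "U" when
    delta > threshold, "D" when delta < -threshold, "-" otherwise
    (comparisons are strict, so a delta exactly at the threshold is "-").
    """
    if sample_a == sample_b:
        raise ConfigurationError("cannot compare a sample with itself")
    for s in (sample_a, sample_b):
        if s not in a.data.columns:
            raise IdentifierError(f"unknown sample {s!r}")
    delta = a.data[sample_b] - a.data[sample_a]
    out = []
    for im_id, d in delta.items():
        call = "U" if d > threshold else ("D" if d < -threshold else "-")
        out.append(
            DifferentialCall(
                imodulon_id=str(im_id),
                condition_pair=(sample_a, sample_b),
                delta_activity=float(d),
                call=call,
            )
        )
    return out


def activity_correlation(
    a: ActivityTable,
    pair: tuple[str, str],
    sample_subset: list[str] | None = None,
) -> tuple[float, float]:
    """Pearson r between two iModulons' activities, with a two-sided p.

    The p-value comes from the t-distribution with n - 2 degrees of freedom
    over the chosen sample subset (all samples by default; at least 3).
    """
    cols = list(sample_subset) if sample_subset is not None else a.sample_ids
    if len(cols) < 3:
        raise ConfigurationError("need at least 3 samples for a correlation")
    u = a.data.loc[pair[0], cols].to_numpy(dtype=float)
    v = a.data.loc[pair[1], cols].to_numpy(dtype=float)
    if u.std() == 0 or v.std() == 0:
        raise UndefinedCorrelationError(
            "zero-variance activity row in the chosen subset"
        )
    res = stats.pearsonr(u, v)
    return float(res.statistic), float(res.pvalue)


def cluster_activities(
    a: ActivityTable,
    linkage: str = "average",
    distance: str = "correlation",
) -> tuple[list[str], np.ndarray]:
    """Hierarchical clustering of iModulon rows by activity similarity.

    Uses 1 - r as the distance (falling back to scaled Euclidean, with a
    warning, for pairs involving a constant row) and the chosen linkage.
    Returns the leaf ordering (iModulon ids) and the scipy merge tree.
    """
    if a.data.shape[0] < 2:
        raise ValueError("need at least 2 iModulons to cluster")
    V = a.data.to_numpy(dtype=float)
    if distance == "correlation":
        sds = V.std(axis=1)
        if (sds == 0).any():
            warnings.warn(
                "constant activity rows: using Euclidean distance for the "
                "affected pairs",
                stacklevel=2,
            )
            D = _mixed_distance(V, sds)
        else:
            D = 1.0 - np.corrcoef(V)
            np.fill_diagonal(D, 0.0)
            D = np.clip(D, 0.0, None)
    else:
        diff = V[:, None, :] - V[None, :, :]
        D = np.sqrt((diff**2).sum(axis=2))
    Z = hierarchy.linkage(squareform(D, checks=False), method=linkage)
    leaves = hierarchy.leaves_list(Z)
    return [a.imodulon_ids[i] for i in leaves], Z


def _mixed_distance(V: np.ndarray, sds: np.ndarray) -> np.ndarray:
    n = V.shape[0]
    D = np.zeros((n, n))
    scale = np.abs(V).max() or 1.0
    for i in range(n):
        for j in range(i + 1, n):
            if sds[i] == 0 or sds[j] == 0:
                d = float(np.linalg.norm(V[i] - V[j])) / scale
            else:
                d = 1.0 - float(np.corrcoef(V[i], V[j])[0, 1])
            D[i, j] = D[j, i] = max(d, 0.0)
    return D
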