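"""From robust components to iModulons.

An iModulon is the thresholded support of one gene-weight column: member
genes are split from the near-Gaussian background of small weights by an
iterative outlier scan based on the D'Agostino K^2 normality statistic.
Each iModulon carries the fraction of the compendium's variance its rank-1
term explains, and structures can be matched against a prior gene-weight
matrix to inherit established names.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegeneracyError, IncompatibilityError, SizeError
from .preprocess import ExpressionMatrix

K2_CUTOFF = 550.0
K2_REFERENCE_GENES = 4322  # genome scale at which the 550 convention is set
MATCH_R_THRESHOLD = 0.7
EV_FILTER = 0.005
_MIN_GENES_FOR_K2 = 20


def default_k2_cutoff(n_genes: int) -> float:
    """Size-aware K^2 cutoff.

    The D'Agostino K^2 statistic grows roughly linearly with the number of
    genes for a fixed departure from normality (both of its squared z-scores
    scale with sample size), so a flat cutoff only makes sense at one
    universe size. The conventional value 550 is calibrated to a bacterial
    genome of ~4.3k genes; it is rescaled proportionally for other sizes.
    """
    return K2_CUTOFF * n_genes / K2_REFERENCE_GENES


@dataclass
class IModulon:
    """One component's thresholded gene set with its bookkeeping."""

    id: str
    weights: pd.Series
    members: set[str]
    threshold: float
    explained_variance: float = float("nan")
    name: str | None = None
    enrichment: object | None = None

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class StructureMatch:
    """One-to-one pairing of two gene-weight structures by |Pearson r|."""

    pairs: list[tuple[str, str, float]] = field(default_factory=list)
    unmatched_new: list[str] = field(default_factory=list)
    unmatched_ref: list[str] = field(default_factory=list)


def _k2_statistic(values: np.ndarray) -> float:
    if np.ptp(values) == 0:  # constant background: no outlier structure left
        return 0.0
    return float(stats.normaltest(values).statistic)


def threshold_genes(
    weights: pd.Series, k2_cutoff: float | None = None
) -> tuple[set[str], float]:
    """Split outlier member genes from the Gaussian weight background.

    Genes are sorted by |weight| descending; the top i genes are removed for
    i = 0, 1, 2, ... until the D'Agostino K^2 statistic of the remaining
    weights drops below ``k2_cutoff`` (`default_k2_cutoff(n_genes)` when
    None). The removed genes are the members; the threshold is the |weight|
    of the last gene removed (+inf when no gene is removed).
    """
    w = weights.to_numpy(dtype=float)
    if len(w) < _MIN_GENES_FOR_K2:
        raise SizeError(
            f"need at least {_MIN_GENES_FOR_K2} genes for the K^2 scan"
        )
    if np.ptp(w) == 0:
        raise DegeneracyError("all weights equal; no outlier structure")
    if k2_cutoff is None:
        k2_cutoff = default_k2_cutoff(len(w))
    order = np.argsort(-np.abs(w), kind="stable")
    max_depth = len(w) - _MIN_GENES_FOR_K2
    for i in range(max_depth + 1):
        if _k2_statistic(w[order[i:]]) < k2_cutoff:
            members = set(weights.index[order[:i]])
            threshold = float(np.abs(w[order[i - 1]])) if i else float("inf")
            return members, threshold
    # background never looks Gaussian: everything scannable is a member
    members = set(weights.index[order[:max_depth]])
    return members, float(np.abs(w[order[max_depth - 1]]))


def threshold_genes_quantile(
    weights: pd.Series, n_sd: float = 3.0
) -> tuple[set[str], float]:
    """Fallback rule for small gene universes: |weight| > mean + n_sd * sd."""
    w = np.abs(weights.to_numpy(dtype=float))
    cut = float(w.mean() + n_sd * w.std(ddof=0))
    members = set(weights.index[w > cut])
    return members, cut


def explained_variance(
    x: ExpressionMatrix, weights: pd.Series, activity_row: pd.Series
) -> float:
    """Fraction of ||X||_F^2 removed by the rank-1 term w a^T (clipped at 0)."""
    X = x.data.loc[weights.index, activity_row.index].to_numpy()
    total = float(np.linalg.norm(X) ** 2)
    if total == 0:
        raise DegeneracyError("zero-norm expression matrix")
    resid = X - np.outer(weights.to_numpy(), activity_row.to_numpy())
    ev = (total - float(np.linalg.norm(resid) ** 2)) / total
    return max(ev, 0.0)


def match_to_reference(
    M_new: pd.DataFrame,
    M_ref: pd.DataFrame,
    r_threshold: float = MATCH_R_THRESHOLD,
) -> StructureMatch:
    """Greedy one-to-one matching of weight columns by |Pearson r|.

    Correlations are computed over the shared gene universe; pairs are taken
    in descending |r|, each side used once, stopping below ``r_threshold``.
    Sign is ignored, so a negated copy of a component still matches it.
    """
    shared = [g for g in M_new.index if g in set(M_ref.index)]
    if not shared:
        raise IncompatibilityError("no genes shared with the reference structure")
    A = M_new.loc[shared].to_numpy(dtype=float)
    B = M_ref.loc[shared].to_numpy(dtype=float)
    n_new, n_ref = A.shape[1], B.shape[1]
    R = np.abs(np.corrcoef(A.T, B.T)[:n_new, n_new:])

    pairs: list[tuple[str, str, float]] = []
    used_new: set[int] = set()
    used_ref: set[int] = set()
    order = np.dstack(np.unravel_index(np.argsort(-R, axis=None), R.shape))[0]
    for i, j in order:
        if R[i, j] < r_threshold:
            break
        if i in used_new or j in used_ref:
            continue
        pairs.append((str(M_new.columns[i]), str(M_ref.columns[j]),
                      float(R[i, j])))
        used_new.add(int(i))
        used_ref.add(int(j))
    return StructureMatch(
        pairs=pairs,
        unmatched_new=[str(c) for k, c in enumerate(M_new.columns)
                       if k not in used_new],
        unmatched_ref=[str(c) for k, c in enumerate(M_ref.columns)
                       if k not in used_ref],
    )


def filter_by_explained_variance(
    imodulons: list[IModulon], min_fraction: float = EV_FILTER
) -> list[IModulon]:
    """Keep iModulons explaining strictly more than ``min_fraction``."""
    return [im for im in imodulons if im.explained_variance > min_fraction]


def build_imodulons(
    S: pd.DataFrame,
    A: pd.DataFrame,
    x: ExpressionMatrix,
    k2_cutoff: float | None = None,
) -> list[IModulon]:
    """Threshold every component of a decomposition and attach its EV."""
    out = []
    small = S.shape[0] < _MIN_GENES_FOR_K2
    for cid in S.columns:
        w = S[cid]
        if small:
            members, thr = threshold_genes_quantile(w)
        else:
            members, thr = threshold_genes(w, k2_cutoff)
        ev = explained_variance(x, w, A.loc[cid])
        out.append(IModulon(id=str(cid), weights=w, members=members,
                            threshold=thr, explained_variance=ev))
    return out


def imodulon_table(imodulons: list[IModulon]) -> pd.DataFrame:
    """Flat summary table (one row per iModulon) for reporting and export."""
    rows = []
    for im in imodulons:
        rec = im.enrichment
        rows.append(
            {
                "id": im.id,
                "name": im.name if im.name is not None else "",
                "n_members": im.size,
                "threshold": im.threshold,
                "explained_variance": im.explained_variance,
                "regulator": getattr(rec, "regulator", ""),
                "q_value": getattr(rec, "q_value", float("nan")),
            }
        )
    return pd.DataFrame(rows).set_index("id")
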