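"""Compendium assembly, reference centering and quality summaries.

The analysis matrix ``X`` is a genes x samples table. New TPM profiles are
concatenated onto a base compendium over the shared gene universe, converted
to log2(TPM + 1), and centered per gene on the mean of a designated set of
reference samples, so that every downstream activity reads as a log2 fold
difference from the reference condition. Replicate agreement (pairwise
Pearson r) and PCA cumulative-variance summaries provide the quality report.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .exceptions import DegeneracyError, IdentifierError, IncompatibilityError

Space = Literal["tpm", "log_centered"]


@dataclass
class ExpressionMatrix:
    """A genes x samples expression table with a unit tag.

    Parameters
    ----------
    data
        DataFrame indexed by gene identifiers with sample identifiers as
        columns. Values are TPM (``space="tpm"``) or centered log2 units
        (``space="log_centered"``).
    space
        Which unit the values are in.
    """

    data: pd.DataFrame
    space: Space = "tpm"

    def __post_init__(self) -> None:
        if self.data.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        if self.data.index.has_duplicates:
            raise IdentifierError("duplicated gene identifiers")
        if self.data.columns.has_duplicates:
            raise IdentifierError("duplicated sample identifiers")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


@dataclass
class QCReport:
    """Replicate-agreement and PCA variance summaries for a compendium."""

    replicate_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    replicate_pass: list[bool] = field(default_factory=list)
    median_replicate_r: float = float("nan")
    pca_cumvar_samples: np.ndarray | None = None
    pca_cumvar_genes: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {
            "replicate_pairs": [
                {"sample_a": a, "sample_b": b, "r": r, "pass": ok}
                for (a, b, r), ok in zip(self.replicate_pairs, self.replicate_pass)
            ],
            "median_replicate_r": self.median_replicate_r,
            "pca_cumvar_samples": (
                None
                if self.pca_cumvar_samples is None
                else [float(v) for v in self.pca_cumvar_samples]
            ),
            "pca_cumvar_genes": (
                None
                if self.pca_cumvar_genes is None
                else [float(v) for v in self.pca_cumvar_genes]
            ),
        }


def assemble_compendium(
    base: ExpressionMatrix, new_samples: ExpressionMatrix
) -> ExpressionMatrix:
    """Concatenate new TPM profiles onto a base compendium.

    Columns are joined on the intersection of the two gene universes, with
    the base matrix's gene order preserved; samples are the disjoint union.
    """
    if base.space != "tpm" or new_samples.space != "tpm":
        raise ValueError("assemble_compendium expects both inputs in tpm space")
    shared = [g for g in base.gene_ids if g in set(new_samples.gene_ids)]
    if not shared:
        raise IncompatibilityError("no genes shared between base and new samples")
    clash = set(base.sample_ids) & set(new_samples.sample_ids)
    if clash:
        raise IdentifierError(f"duplicated sample identifiers: {sorted(clash)[:5]}")
    merged = pd.concat(
        [base.data.loc[shared], new_samples.data.loc[shared]], axis=1
    )
    return ExpressionMatrix(merged, space="tpm")


def log_center(
    tpm: ExpressionMatrix,
    reference_sample_ids: list[str],
    pseudocount: float = 1.0,
) -> ExpressionMatrix:
    """log2(TPM + pseudocount), then center each gene on the reference mean.

    After centering, the mean over the reference samples is zero for every
    gene, so values read as log2 fold changes from the reference condition.
    """
    if tpm.space != "tpm":
        raise ValueError("log_center expects a tpm-space matrix")
    if not reference_sample_ids:
        raise IdentifierError("reference sample list is empty")
    missing = set(reference_sample_ids) - set(tpm.sample_ids)
    if missing:
        raise IdentifierError(f"unknown reference samples: {sorted(missing)}")
    logged = np.log2(tpm.data + pseudocount)
    centered = logged.sub(logged[list(reference_sample_ids)].mean(axis=1), axis=0)
    return ExpressionMatrix(centered, space="log_centered")


def replicate_qc(
    x: ExpressionMatrix,
    metadata: pd.DataFrame,
    min_r: float = 0.95,
) -> QCReport:
    """Pearson r for every within-(condition, time) replicate pair.

    ``metadata`` must be indexed by (or contain a ``sample_id`` column of)
    sample identifiers with ``condition`` and ``time_h`` columns. A pair
    fails when r < ``min_r``; a group with a single sample only warns.
    """
    meta = metadata.copy()
    if "sample_id" in meta.columns:
        meta = meta.set_index("sample_id")
    meta = meta.loc[[s for s in x.sample_ids if s in meta.index]]
    pairs: list[tuple[str, str, float]] = []
    passes: list[bool] = []
    for (_, _), group in meta.groupby(["condition", "time_h"], sort=True):
        samples = list(group.index)
        if len(samples) < 2:
            warnings.warn(
                f"group with a single sample: {samples}", stacklevel=2
            )
            continue
        for i in range(len(samples)):
            for j in range(i + 1, len(samples)):
                a = x.data[samples[i]].to_numpy()
                b = x.data[samples[j]].to_numpy()
                r = float(np.corrcoef(a, b)[0, 1])
                pairs.append((samples[i], samples[j], r))
                passes.append(r >= min_r)
    median = float(np.median([r for _, _, r in pairs])) if pairs else float("nan")
    return QCReport(
        replicate_pairs=pairs, replicate_pass=passes, median_replicate_r=median
    )


def pca_summary(
    x: ExpressionMatrix, mode: Literal["samples", "genes"] = "samples"
) -> np.ndarray:
    """Cumulative explained-variance fractions of a PCA of the compendium.

    ``mode="samples"`` treats samples as observations in gene space (per-gene
    centering across samples); ``mode="genes"`` transposes the roles.
    """
    if x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("pca_summary needs at least a 2 x 2 matrix")
    mat = x.values if mode == "genes" else x.values.T
    # rows = observations, columns = variables; center variables
    mat = mat - mat.mean(axis=0, keepdims=True)
    sv = np.linalg.svd(mat, compute_uv=False)
    var = sv**2
    total = var.sum()
    if total <= 0:
        raise DegeneracyError("constant matrix has no variance to decompose")
    cum = np.cumsum(var) / total
    cum[-1] = 1.0  # guard rounding so the sequence ends exactly at 1
    return cum
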