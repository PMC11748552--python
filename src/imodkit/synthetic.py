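"""Synthetic expression compendia with planted module structure.

The generator is the study-design counterpart of the decomposition model
``X = M A``: it plants sparse, heavy-tailed gene-weight columns (``M_true``),
smooth condition/time activity trajectories (``A_true``), adds i.i.d.
Gaussian noise in log space, and maps the result to TPM space by adding
per-gene baselines and rescaling every sample to a fixed library size. A
transcriptional regulatory network aligned to the planted modules (with
controllable fidelity, plus decoy regulators) supports enrichment testing,
and `score_recovery` measures how well a fitted structure finds the plant.

Trajectory shapes emulate nutrient-starvation time courses: sigmoidal
induction/repression around entry into stationary phase, transient pulses,
and flat housekeeping activity; declared module pairs can be exactly
anti-correlated. A block of "background" samples with i.i.d. random
activities plays the role of the large reference compendium that the
time-course samples are concatenated with and centered on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, ShapeError, SizingError
from .preprocess import ExpressionMatrix

TRAJECTORY_KINDS = ("flat", "sigmoid-up", "sigmoid-down", "transient-pulse")

BACKGROUND_CONDITION = "base"
LIBRARY_SIZE = 1e6


@dataclass
class SampleDesign:
    """Condition x time x replicate layout of a simulated experiment.

    ``reference`` designates exactly one (condition, time) pair whose samples
    are the centering reference. ``background_samples`` adds that many extra
    compendium-style samples under condition ``"base"`` at time 0 with
    i.i.d. random module activities; when present they normally serve as the
    reference block.
    """

    conditions: list[str]
    timepoints: list[float]
    replicates: int
    reference: tuple[str, float]
    background_samples: int = 0

    def __post_init__(self) -> None:
        cond, t = self.reference
        designed = cond in self.conditions and float(t) in [
            float(v) for v in self.timepoints
        ]
        in_background = cond == BACKGROUND_CONDITION and self.background_samples > 0
        if not (designed or in_background):
            raise ConfigurationError(
                f"reference {self.reference!r} names no sample group"
            )

    @property
    def n_designed(self) -> int:
        return len(self.conditions) * len(self.timepoints) * self.replicates

    @property
    def n_samples(self) -> int:
        return self.n_designed + self.background_samples

    def metadata(self) -> pd.DataFrame:
        """Sample table: sample_id, condition, time_h, replicate, is_reference."""
        rows = []
        for i in range(self.background_samples):
            rows.append((f"{BACKGROUND_CONDITION}_{i + 1:03d}",
                         BACKGROUND_CONDITION, 0.0, i + 1))
        for cond in self.conditions:
            for t in self.timepoints:
                for rep in range(1, self.replicates + 1):
                    rows.append((f"{cond}_t{t:g}_r{rep}", cond, float(t), rep))
        meta = pd.DataFrame(
            rows, columns=["sample_id", "condition", "time_h", "replicate"]
        )
        ref_cond, ref_t = self.reference
        meta["is_reference"] = (meta["condition"] == ref_cond) & (
            meta["time_h"] == float(ref_t)
        )
        return meta


@dataclass
class GroundTruth:
    """Planted structure behind a synthetic compendium.

    ``memberships[k]`` is exactly the nonzero support of column k of
    ``M_true``; columns of ``M_true`` have unit Euclidean norm.
    """

    M_true: pd.DataFrame
    memberships: list[set[str]]
    A_true: pd.DataFrame | None = None
    trn_true: dict[str, set[str]] = field(default_factory=dict)
    noise_sd: float = 0.0
    seed: int = 0

    @property
    def gene_ids(self) -> list[str]:
        return list(self.M_true.index)

    @property
    def k_modules(self) -> int:
        return self.M_true.shape[1]

    def validate(self) -> None:
        M = self.M_true.to_numpy()
        norms = np.linalg.norm(M, axis=0)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("M_true columns are not unit norm")
        for k, members in enumerate(self.memberships):
            support = set(self.M_true.index[M[:, k] != 0])
            if support != members:
                raise ValueError(f"membership {k} does not match M_true support")
        universe = set(self.gene_ids)
        for reg, targets in self.trn_true.items():
            if not targets <= universe:
                raise ValueError(f"regulon {reg} leaves the gene universe")


def _module_ids(k: int) -> list[str]:
    return [f"mod_{i:02d}" for i in range(k)]


def generate_structure(
    n_genes: int,
    k_modules: int,
    genes_per_module: int | tuple[int, int],
    weight_scale: float = 1.0,
    overlap_allowed: bool = False,
    seed: int = 0,
    min_weight: float = 0.1,
) -> GroundTruth:
    """Plant ``k_modules`` sparse unit-norm gene-weight columns.

    Member weights are heavy-tailed (Laplace magnitudes plus a minimum-
    magnitude floor, random sign) so the columns are non-Gaussian — the
    identifiability requirement for ICA; non-members are exactly zero.
    """
    rng = np.random.default_rng(seed)
    if isinstance(genes_per_module, int):
        lo = hi = genes_per_module
    else:
        lo, hi = genes_per_module
    if not overlap_allowed and k_modules * lo > n_genes:
        raise SizingError(
            f"{k_modules} disjoint modules of >= {lo} genes need more than "
            f"{n_genes} genes"
        )
    sizes = [int(rng.integers(lo, hi + 1)) for _ in range(k_modules)]
    if not overlap_allowed and sum(sizes) > n_genes:
        raise SizingError("drawn module sizes exceed the gene universe")

    genes = [f"g{i + 1:04d}" for i in range(n_genes)]
    pool = np.arange(n_genes)
    memberships: list[set[str]] = []
    M = np.zeros((n_genes, k_modules))
    for k, size in enumerate(sizes):
        if overlap_allowed:
            idx = rng.choice(n_genes, size=size, replace=False)
        else:
            idx = rng.choice(pool, size=size, replace=False)
            pool = np.setdiff1d(pool, idx)
        signs = rng.choice([-1.0, 1.0], size=size)
        mags = min_weight + rng.exponential(1.0, size=size)  # Laplace magnitude
        w = signs * mags * weight_scale
        w /= np.linalg.norm(w)
        M[idx, k] = w
        memberships.append({genes[i] for i in idx})
    M_true = pd.DataFrame(M, index=genes, columns=_module_ids(k_modules))
    return GroundTruth(M_true=M_true, memberships=memberships, seed=seed)


def _trajectory(kind: str, t: np.ndarray, rng: np.random.Generator,
                amplitude: float) -> np.ndarray:
    scale = amplitude * rng.uniform(0.5, 1.0)
    span = t.max() - t.min() if t.max() > t.min() else 1.0
    t0 = rng.uniform(t.min() + 0.2 * span, t.min() + 0.8 * span)
    tau = rng.uniform(0.1, 0.3) * span
    if kind == "flat":
        return np.full_like(t, amplitude, dtype=float)
    if kind == "sigmoid-up":
        return scale / (1.0 + np.exp(-(t - t0) / tau))
    if kind == "sigmoid-down":
        return scale / (1.0 + np.exp((t - t0) / tau))
    if kind == "transient-pulse":
        return scale * np.exp(-(((t - t0) / tau) ** 2))
    raise ConfigurationError(f"unknown trajectory kind {kind!r}")


def generate_activities(
    design: SampleDesign,
    k_modules: int,
    trajectory_kinds: tuple[str, ...] = TRAJECTORY_KINDS,
    anticorrelated_pairs: list[tuple[int, int]] = (),
    amplitude: float = 5.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Smooth per-condition activity trajectories for each planted module.

    Each (module, condition) draws a shape from ``trajectory_kinds`` with
    random midpoint/steepness, evaluated at the design's timepoints and
    repeated across replicates. Background samples get i.i.d. Gaussian
    activities (sd = amplitude / 2). For every pair (a, b) in
    ``anticorrelated_pairs`` the full row b is set to the negation of row a.
    """
    for kind in trajectory_kinds:
        if kind not in TRAJECTORY_KINDS:
            raise ConfigurationError(f"unknown trajectory kind {kind!r}")
    for a, b in anticorrelated_pairs:
        if a >= k_modules or b >= k_modules:
            raise ConfigurationError("anticorrelated pair index out of range")
    rng = np.random.default_rng(seed)
    meta = design.metadata()
    t = np.asarray(design.timepoints, dtype=float)
    A = np.zeros((k_modules, len(meta)))
    bg = meta["condition"] == BACKGROUND_CONDITION
    for k in range(k_modules):
        A[k, bg.to_numpy()] = rng.normal(0.0, amplitude / 2.0, int(bg.sum()))
        for cond in design.conditions:
            kind = str(rng.choice(list(trajectory_kinds)))
            traj = _trajectory(kind, t, rng, amplitude)
            for ti, tv in enumerate(design.timepoints):
                mask = (meta["condition"] == cond) & (meta["time_h"] == float(tv))
                A[k, mask.to_numpy()] = traj[ti]
    for a, b in anticorrelated_pairs:
        A[b] = -A[a]
    return pd.DataFrame(A, index=_module_ids(k_modules),
                        columns=list(meta["sample_id"]))


def synthesize_expression(
    gt: GroundTruth,
    design: SampleDesign,
    baseline_log2_range: tuple[float, float] = (3.0, 10.0),
    library_size: float = LIBRARY_SIZE,
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Forward model: centered log matrix ``X = M A + E`` and its TPM image.

    The TPM-space matrix adds a per-gene baseline in log2 units,
    exponentiates, and rescales every sample column to ``library_size``.
    Both outputs share the same noise realization; with ``noise_sd = 0`` the
    centered matrix equals ``M_true @ A_true`` exactly.
    """
    if gt.A_true is None:
        raise ShapeError("ground truth has no activity matrix")
    if gt.M_true.shape[1] != gt.A_true.shape[0]:
        raise ShapeError(
            f"M_true has {gt.M_true.shape[1]} modules but A_true has "
            f"{gt.A_true.shape[0]} rows"
        )
    rng = np.random.default_rng(np.random.SeedSequence([int(gt.seed), 7]))
    M = gt.M_true.to_numpy()
    A = gt.A_true.to_numpy()
    signal = M @ A
    E = rng.normal(0.0, gt.noise_sd, signal.shape) if gt.noise_sd > 0 else 0.0
    X = signal + E
    centered = pd.DataFrame(X, index=gt.gene_ids, columns=list(gt.A_true.columns))

    baselines = rng.uniform(*baseline_log2_range, size=len(gt.gene_ids))
    linear = np.exp2(X + baselines[:, None])
    tpm = linear * (library_size / linear.sum(axis=0, keepdims=True))
    tpm_df = pd.DataFrame(tpm, index=gt.gene_ids, columns=list(gt.A_true.columns))
    return (
        ExpressionMatrix(centered, space="log_centered"),
        ExpressionMatrix(tpm_df, space="tpm"),
    )


def generate_trn(
    gt: GroundTruth,
    fidelity: float = 1.0,
    n_decoy_regulators: int = 0,
    decoy_size: int = 10,
    seed: int = 0,
) -> dict[str, set[str]]:
    """A regulator -> target-set map aligned to the plant with given fidelity.

    One regulator per module keeps each true member with probability
    ``fidelity``; dropped members are replaced with random non-members so
    regulon size is preserved. Decoy regulators get random gene sets.
    """
    if not 0.0 <= fidelity <= 1.0:
        raise ConfigurationError("fidelity must be in [0, 1]")
    if n_decoy_regulators and decoy_size > len(gt.gene_ids):
        raise SizingError("decoy_size exceeds the gene universe")
    rng = np.random.default_rng(seed)
    genes = np.array(gt.gene_ids)
    trn: dict[str, set[str]] = {}
    for k, members in enumerate(gt.memberships):
        member_list = sorted(members)
        keep = [g for g in member_list if rng.random() < fidelity]
        n_replace = len(member_list) - len(keep)
        non_members = np.array(sorted(set(genes) - members))
        extra = rng.choice(non_members, size=n_replace, replace=False)
        trn[f"Reg{k:02d}"] = set(keep) | set(extra.tolist())
    for j in range(n_decoy_regulators):
        trn[f"Decoy{j:02d}"] = set(
            rng.choice(genes, size=decoy_size, replace=False).tolist()
        )
    return trn


def signal_noise_sd(gt: GroundTruth, ratio: float = 0.25) -> float:
    """Noise sd as a fraction of the median per-gene signal sd.

    The median is taken over module-member genes only; non-members carry no
    signal and would drag it to zero.
    """
    if gt.A_true is None:
        raise ShapeError("ground truth has no activity matrix")
    signal = gt.M_true.to_numpy() @ gt.A_true.to_numpy()
    member_mask = (gt.M_true.to_numpy() != 0).any(axis=1)
    per_gene_sd = signal[member_mask].std(axis=1, ddof=0)
    return float(ratio * np.median(per_gene_sd))


def simulate_compendium(
    n_genes: int = 300,
    k_modules: int = 10,
    genes_per_module: int | tuple[int, int] = 15,
    conditions: list[str] = ("C-lim", "N-lim", "S-lim"),
    timepoints: list[float] = (3, 4, 6, 8, 12, 24),
    replicates: int = 2,
    background_samples: int = 30,
    amplitude: float = 5.0,
    trajectory_kinds: tuple[str, ...] = ("sigmoid-up", "sigmoid-down",
                                         "transient-pulse"),
    anticorrelated_pairs: list[tuple[int, int]] = (),
    noise_ratio: float = 0.25,
    trn_fidelity: float = 1.0,
    n_decoy_regulators: int = 5,
    decoy_size: int = 10,
    seed: int = 0,
) -> dict:
    """One-call synthetic study: structure, activities, expression, TRN.

    Defaults mirror a starvation time course: three element-limiting
    conditions sampled over a day with two biological replicates, appended to
    a 30-sample background block that serves as the centering reference.
    Noise sd is ``noise_ratio`` times the median per-gene signal sd.
    Returns a dict with keys ``gt``, ``design``, ``metadata``, ``centered``,
    ``tpm``, ``trn``.
    """
    rng = np.random.default_rng(seed)
    sub = [int(s) for s in rng.integers(0, 2**31 - 1, size=3)]
    ref = (BACKGROUND_CONDITION, 0.0) if background_samples else (
        conditions[0], float(timepoints[0])
    )
    design = SampleDesign(
        conditions=list(conditions),
        timepoints=[float(t) for t in timepoints],
        replicates=replicates,
        reference=ref,
        background_samples=background_samples,
    )
    gt = generate_structure(
        n_genes, k_modules, genes_per_module, seed=sub[0]
    )
    gt.A_true = generate_activities(
        design,
        k_modules,
        trajectory_kinds=trajectory_kinds,
        anticorrelated_pairs=anticorrelated_pairs,
        amplitude=amplitude,
        seed=sub[1],
    )
    gt.noise_sd = signal_noise_sd(gt, noise_ratio)
    gt.seed = seed
    centered, tpm = synthesize_expression(gt, design)
    gt.trn_true = generate_trn(
        gt,
        fidelity=trn_fidelity,
        n_decoy_regulators=n_decoy_regulators,
        decoy_size=decoy_size,
        seed=sub[2],
    )
    return {
        "gt": gt,
        "design": design,
        "metadata": design.metadata(),
        "centered": centered,
        "tpm": tpm,
        "trn": gt.trn_true,
    }


def score_recovery(
    gt: GroundTruth,
    recovered_members: list[set[str]],
    A_recovered: pd.DataFrame | None = None,
) -> dict:
    """Greedy best-match scoring of a fitted structure against the plant.

    Matches recovered member sets to planted memberships by descending
    membership F1 (each side used once); unmatched planted modules score 0.
    When ``A_recovered`` is given (components x samples, columns aligned by
    sample id with ``gt.A_true``), the matched pairs' absolute activity
    Pearson correlations are reported as well.
    """
    k_true = len(gt.memberships)
    k_rec = len(recovered_members)
    f1 = np.zeros((k_rec, k_true))
    for i, rec in enumerate(recovered_members):
        for j, true in enumerate(gt.memberships):
            inter = len(rec & true)
            if inter:
                p = inter / len(rec)
                r = inter / len(true)
                f1[i, j] = 2 * p * r / (p + r)
    pairs: list[tuple[int, int, float]] = []
    used_i: set[int] = set()
    used_j: set[int] = set()
    order = np.dstack(np.unravel_index(np.argsort(-f1, axis=None), f1.shape))[0]
    for i, j in order:
        if i in used_i or j in used_j or f1[i, j] <= 0:
            continue
        pairs.append((int(i), int(j), float(f1[i, j])))
        used_i.add(int(i))
        used_j.add(int(j))
    f1_per_true = np.zeros(k_true)
    for i, j, v in pairs:
        f1_per_true[j] = v

    out = {
        "pairs": pairs,
        "f1_per_module": f1_per_true.tolist(),
        "median_f1": float(np.median(f1_per_true)) if k_true else float("nan"),
    }
    if A_recovered is not None and gt.A_true is not None:
        shared = [s for s in gt.A_true.columns if s in set(A_recovered.columns)]
        corr = np.zeros(k_true)
        for i, j, _ in pairs:
            a = A_recovered.iloc[i][shared].to_numpy(dtype=float)
            b = gt.A_true.iloc[j][shared].to_numpy(dtype=float)
            if a.std() > 0 and b.std() > 0:
                corr[j] = abs(float(np.corrcoef(a, b)[0, 1]))
        out["activity_abs_corr_per_module"] = corr.tolist()
        out["n_activity_corr_ge_095"] = int((corr >= 0.95).sum())
    return out
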