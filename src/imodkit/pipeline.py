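"""End-to-end orchestration: simulate/read -> center -> decompose -> annotate.

A single `PipelineConfig` drives every stage; each stage writes its artifact
under the output directory so downstream thresholds (explained-variance
filter, differential-activity threshold) can be iterated without repeating
the expensive decomposition. With fixed seeds the whole run is
deterministic, down to the bytes of the written matrices.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io
from .activities import (
    ActivityTable,
    average_replicates,
    cluster_activities,
    differential_calls,
    infer_activities,
    normalize_to_reference,
)
from .enrichment import FDR_DEFAULT, enrich_all
from .exceptions import ConfigurationError
from .ica import optica, robust_components
from .preprocess import ExpressionMatrix, log_center, pca_summary, replicate_qc
from .structure import (
    EV_FILTER,
    MATCH_R_THRESHOLD,
    build_imodulons,
    filter_by_explained_variance,
    imodulon_table,
    match_to_reference,
)
from .synthetic import BACKGROUND_CONDITION, simulate_compendium, score_recovery

logger = logging.getLogger("imodkit")


@dataclass
class PipelineConfig:
    """Everything a full run needs; exactly one of ``simulate``/``tpm_path``."""

    out_dir: str = "imodkit_out"
    seed: int = 0
    # inputs: either a simulate block (kwargs of simulate_compendium) ...
    simulate: dict | None = None
    # ... or paths to on-disk inputs
    tpm_path: str | None = None
    metadata_path: str | None = None
    trn_path: str | None = None
    prior_structure_path: str | None = None
    # decomposition
    dim: int | None = None
    dim_grid: list[int] | None = None
    n_runs: int = 10
    cluster_radius: float = 0.3
    min_fraction: float = 0.5
    # thresholds
    k2_cutoff: float | None = None
    fdr: float = FDR_DEFAULT
    match_r: float = MATCH_R_THRESHOLD
    ev_filter: float = EV_FILTER
    diff_threshold: float = 5.0
    min_replicate_r: float = 0.95
    # label "{condition}_t{time}" of the replicate-averaged activity reference
    activity_reference: str | None = None

    def validate(self) -> None:
        if (self.simulate is None) == (self.tpm_path is None):
            raise ConfigurationError(
                "exactly one of a simulate block or a tpm path is required"
            )
        if self.tpm_path is not None:
            for label, p in [("tpm", self.tpm_path),
                             ("metadata", self.metadata_path),
                             ("trn", self.trn_path)]:
                if p is None or not Path(p).exists():
                    raise ConfigurationError(f"missing {label} input: {p}")
        if self.prior_structure_path is not None and not Path(
            self.prior_structure_path
        ).exists():
            raise ConfigurationError(
                f"prior structure not found: {self.prior_structure_path}"
            )
        if self.dim is None and not self.dim_grid:
            raise ConfigurationError("set dim or dim_grid")
        if not (0 < self.match_r <= 1):
            raise ConfigurationError("match_r must be in (0, 1]")
        if not (0 < self.fdr < 1):
            raise ConfigurationError("fdr must be in (0, 1)")
        if not (0 < self.cluster_radius < 1):
            raise ConfigurationError("cluster_radius must be in (0, 1)")
        if self.ev_filter < 0 or self.diff_threshold < 0:
            raise ConfigurationError("thresholds must be non-negative")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return {
            f: getattr(self, f)
            for f in self.__dataclass_fields__
            if getattr(self, f) is not None
        }


@dataclass
class ResultBundle:
    """In-memory handles to every stage artifact of one pipeline run."""

    out_dir: Path
    config: PipelineConfig
    x: ExpressionMatrix
    metadata: pd.DataFrame
    qc: object
    component_set: object
    optica_diagnostics: pd.DataFrame | None
    imodulons: list
    imodulons_filtered: list
    enrichment_records: list
    activities_raw: ActivityTable
    activities_ref: ActivityTable
    diff_calls: pd.DataFrame
    leaf_order: list[str] | None
    recovery: dict | None = None
    ground_truth: object = None


def _stage(name: str):
    logger.info("stage: %s", name)
    return time.perf_counter()


def run_pipeline(config: PipelineConfig) -> ResultBundle:
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # ------------------------------------------------------------- inputs
    t0 = _stage("inputs")
    gt = None
    if config.simulate is not None:
        sim_kwargs = dict(config.simulate)
        sim_kwargs.setdefault("seed", config.seed)
        sim = simulate_compendium(**sim_kwargs)
        gt, metadata = sim["gt"], sim["metadata"]
        tpm, trn = sim["tpm"], sim["trn"]
        io.write_expression(tpm, out / "tpm.tsv")
        io.write_metadata(metadata, out / "metadata.tsv")
        io.write_trn(trn, out / "trn.tsv")
        io.save_ground_truth(gt, out / "ground_truth")
    else:
        tpm = io.read_expression(config.tpm_path, space="tpm")
        metadata = io.read_metadata(config.metadata_path)
        trn = io.read_trn(config.trn_path)

    # --------------------------------------------------------- preprocess
    logger.info("inputs done in %.1fs", time.perf_counter() - t0)
    t0 = _stage("preprocess")
    ref_ids = list(metadata.loc[metadata["is_reference"], "sample_id"])
    x = log_center(tpm, ref_ids)
    qc_meta = metadata[metadata["condition"] != BACKGROUND_CONDITION]
    qc = replicate_qc(x, qc_meta, min_r=config.min_replicate_r)
    qc.pca_cumvar_samples = pca_summary(x, mode="samples")
    qc.pca_cumvar_genes = pca_summary(x, mode="genes")
    io.write_expression(x, out / "X.tsv")
    (out / "qc.json").write_text(json.dumps(io.to_json_safe(qc.to_dict()),
                                            indent=1))

    # ---------------------------------------------------------- decompose
    logger.info("preprocess done in %.1fs", time.perf_counter() - t0)
    t0 = _stage("decompose")
    rng = np.random.default_rng(config.seed)
    run_seeds = [int(s) for s in rng.integers(0, 2**31 - 1, config.n_runs)]
    diag = None
    if config.dim_grid:
        dim, diag = optica(
            x, list(config.dim_grid), n_runs=config.n_runs, seeds=run_seeds,
            cluster_radius=config.cluster_radius,
            min_fraction=config.min_fraction,
        )
        diag.to_csv(out / "optica_diagnostics.tsv", sep="\t")
    else:
        dim = int(config.dim)
    cs = robust_components(
        x, dim, n_runs=config.n_runs, seeds=run_seeds,
        cluster_radius=config.cluster_radius, min_fraction=config.min_fraction,
    )
    io.save_structure(cs, out / "structure")
    decomp_info = {"selected_dim": dim, "n_robust": cs.n_components,
                   "explained_variance_total": cs.explained_variance_total(x)}
    (out / "decomposition.json").write_text(
        json.dumps(io.to_json_safe(decomp_info), indent=1)
    )

    # ---------------------------------------------------------- structure
    logger.info("decompose done in %.1fs", time.perf_counter() - t0)
    t0 = _stage("structure")
    imodulons = build_imodulons(cs.S, cs.A, x, k2_cutoff=config.k2_cutoff)
    inherited: dict[str, str] = {}
    if config.prior_structure_path is not None:
        prior = io.load_structure(config.prior_structure_path)
        match = match_to_reference(cs.S, prior.S, r_threshold=config.match_r)
        inherited = {new: ref for new, ref, _ in match.pairs}

    # ------------------------------------------------------------- enrich
    records = enrich_all(
        imodulons, trn, universe=set(x.gene_ids), fdr=config.fdr
    )
    for im in imodulons:  # prior names take precedence over enrichment names
        if im.id in inherited:
            im.name = inherited[im.id]
    imods_filtered = filter_by_explained_variance(imodulons, config.ev_filter)
    table = imodulon_table(imodulons)
    table["passes_ev_filter"] = [im.explained_variance > config.ev_filter
                                 for im in imodulons]
    table.to_csv(out / "imodulon_table.tsv", sep="\t")
    io.write_gmt({im.id: im.members for im in imodulons}, out / "members.gmt")
    if records:
        pd.DataFrame([r.__dict__ for r in records]).to_csv(
            out / "enrichment.tsv", sep="\t", index=False
        )

    # ---------------------------------------------------------- activities
    logger.info("structure+enrich done in %.1fs", time.perf_counter() - t0)
    t0 = _stage("activities")
    act = infer_activities(cs.S, x)
    averaged = average_replicates(act, metadata)
    ref_label = config.activity_reference
    if ref_label is None:
        designed = metadata[metadata["condition"] != BACKGROUND_CONDITION]
        cond = sorted(designed["condition"].unique())[0]
        t_min = designed.loc[designed["condition"] == cond, "time_h"].min()
        ref_label = f"{cond}_t{t_min:g}"
    act_ref = normalize_to_reference(averaged, ref_label)
    io.write_matrix(act.data, out / "activities.tsv", index_label="imodulon")
    io.write_matrix(act_ref.data, out / "activities_ref.tsv",
                    index_label="imodulon")

    calls = []
    for col in act_ref.sample_ids:
        if col == ref_label:
            continue
        for c in differential_calls(act_ref, ref_label, col,
                                    threshold=config.diff_threshold):
            calls.append({"imodulon": c.imodulon_id, "comparison": col,
                          "delta": c.delta_activity, "call": c.call})
    diff_df = pd.DataFrame(calls)
    diff_df.to_csv(out / "diff_calls.tsv", sep="\t", index=False)

    leaf_order = None
    if len(imods_filtered) >= 2:
        sub = ActivityTable(
            act_ref.data.loc[[im.id for im in imods_filtered]],
            normalization=act_ref.normalization,
        )
        leaf_order, _ = cluster_activities(sub)
        (out / "clustering.json").write_text(json.dumps(leaf_order, indent=1))

    # ------------------------------------------------------------ recovery
    recovery = None
    if gt is not None:
        recovery = score_recovery(
            gt, [im.members for im in imodulons], A_recovered=cs.A
        )
        recovery["optica_selected_dim"] = dim
        planted_regs = set(gt.trn_true) - {
            r for r in gt.trn_true if r.startswith("Decoy")
        }
        named_by_planted = 0
        for i, j, _ in recovery["pairs"]:
            if imodulons[i].name == f"Reg{j:02d}":
                named_by_planted += 1
        recovery["n_named_by_planted_regulator"] = named_by_planted
        recovery["n_planted_regulators"] = len(planted_regs)
        (out / "recovery.json").write_text(
            json.dumps(io.to_json_safe(recovery), indent=1)
        )

    # -------------------------------------------------------------- echo
    logger.info("activities done in %.1fs", time.perf_counter() - t0)
    echo = {"config": io.to_json_safe(config.to_dict()),
            "run_seeds": run_seeds}
    (out / "config_echo.yaml").write_text(yaml.safe_dump(echo, sort_keys=True))

    return ResultBundle(
        out_dir=out,
        config=config,
        x=x,
        metadata=metadata,
        qc=qc,
        component_set=cs,
        optica_diagnostics=diag,
        imodulons=imodulons,
        imodulons_filtered=imods_filtered,
        enrichment_records=records,
        activities_raw=act,
        activities_ref=act_ref,
        diff_calls=diff_df,
        leaf_order=leaf_order,
        recovery=recovery,
        ground_truth=gt,
    )
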