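"""Plain-text artifact formats: TSV matrices, GMT regulons, JSON bundles.

All matrices are tab-separated with a header row of sample (or component)
identifiers and the first column holding gene identifiers; floats are
written at full round-trip precision so save/load is exact.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ParseError
from .ica import ComponentSet
from .preprocess import ExpressionMatrix
from .synthetic import GroundTruth

_FLOAT_FMT = "%.17g"


def write_matrix(df: pd.DataFrame, path: str | Path, index_label: str = "gene_id"
                 ) -> None:
    df.to_csv(path, sep="\t", index_label=index_label,
              float_format=_FLOAT_FMT)


def read_matrix(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # pragma: no cover - message wrapping
        raise ParseError(f"cannot parse matrix file {path}: {exc}") from exc
    if df.empty and df.columns.empty:
        raise ParseError(f"matrix file {path} is empty")
    return df


def write_expression(x: ExpressionMatrix, path: str | Path) -> None:
    write_matrix(x.data, path)


def read_expression(path: str | Path, space: str) -> ExpressionMatrix:
    return ExpressionMatrix(read_matrix(path), space=space)


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index=False)


def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t")
    required = {"sample_id", "condition", "time_h", "replicate", "is_reference"}
    missing = required - set(meta.columns)
    if missing:
        raise ParseError(f"metadata missing columns: {sorted(missing)}")
    return meta


def write_trn(trn: dict[str, set[str]], path: str | Path) -> None:
    """Two-column (regulator, gene) tab-separated file."""
    with open(path, "w") as fh:
        fh.write("regulator\tgene\n")
        for reg in sorted(trn):
            for gene in sorted(trn[reg]):
                fh.write(f"{reg}\t{gene}\n")


def read_trn(path: str | Path) -> dict[str, set[str]]:
    """Read a TRN from two-column TSV or GMT (detected from the first line)."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise ParseError(f"empty TRN file {path}")
    trn: dict[str, set[str]] = {}
    first = lines[0].split("\t")
    if len(first) == 2 and first[1].strip().lower() == "gene":
        for ln, line in enumerate(lines[1:], start=2):
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(f"{path}:{ln}: expected 2 columns")
            trn.setdefault(parts[0], set()).add(parts[1])
    else:  # GMT: regulator <tab> description <tab> gene...
        for ln, line in enumerate(lines, start=1):
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{ln}: GMT line needs >= 3 fields")
            trn[parts[0]] = set(parts[2:])
    return trn


def write_gmt(sets: dict[str, set[str]], path: str | Path,
              description: str = "imodkit") -> None:
    with open(path, "w") as fh:
        for name in sorted(sets):
            genes = "\t".join(sorted(sets[name]))
            fh.write(f"{name}\t{description}\t{genes}\n")


def save_ground_truth(gt: GroundTruth, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_matrix(gt.M_true, outdir / "M_true.tsv")
    if gt.A_true is not None:
        write_matrix(gt.A_true, outdir / "A_true.tsv", index_label="module")
    bundle = {
        "memberships": [sorted(m) for m in gt.memberships],
        "trn_true": {r: sorted(g) for r, g in gt.trn_true.items()},
        "noise_sd": gt.noise_sd,
        "seed": int(gt.seed),
    }
    (outdir / "ground_truth.json").write_text(json.dumps(bundle, indent=1))


def load_ground_truth(outdir: str | Path) -> GroundTruth:
    outdir = Path(outdir)
    bundle = json.loads((outdir / "ground_truth.json").read_text())
    M = read_matrix(outdir / "M_true.tsv")
    a_path = outdir / "A_true.tsv"
    A = read_matrix(a_path) if a_path.exists() else None
    return GroundTruth(
        M_true=M,
        A_true=A,
        memberships=[set(m) for m in bundle["memberships"]],
        trn_true={r: set(g) for r, g in bundle["trn_true"].items()},
        noise_sd=float(bundle["noise_sd"]),
        seed=int(bundle["seed"]),
    )


def save_structure(cs: ComponentSet, outdir: str | Path) -> None:
    """Write S (the M matrix), A, and run provenance under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_matrix(cs.S, outdir / "M.tsv")
    write_matrix(cs.A, outdir / "A.tsv", index_label="component")
    meta = {
        "dim_requested": int(cs.dim_requested),
        "run_seeds": [int(s) for s in cs.run_seeds],
        "reproducibility": [float(r) for r in cs.reproducibility],
        "converged": bool(cs.converged),
    }
    (outdir / "structure.json").write_text(json.dumps(meta, indent=1))


def load_structure(outdir: str | Path) -> ComponentSet:
    outdir = Path(outdir)
    S = read_matrix(outdir / "M.tsv")
    A = read_matrix(outdir / "A.tsv")
    try:
        meta = json.loads((outdir / "structure.json").read_text())
    except FileNotFoundError as exc:
        raise ParseError(f"missing structure.json in {outdir}") from exc
    if list(S.columns) != list(A.index):
        raise ParseError(
            f"component ids disagree between M ({list(S.columns)[:3]}...) "
            f"and A ({list(A.index)[:3]}...)"
        )
    if S.isna().any().any() or A.isna().any().any():
        raise ParseError("structure matrices contain missing values")
    return ComponentSet(
        S=S,
        A=A,
        dim_requested=int(meta["dim_requested"]),
        run_seeds=[int(s) for s in meta["run_seeds"]],
        reproducibility=[float(r) for r in meta["reproducibility"]],
        converged=bool(meta.get("converged", True)),
    )


def to_json_safe(obj):
    """Recursively convert numpy scalars/arrays for json.dumps."""
    if isinstance(obj, dict):
        return {str(k): to_json_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [to_json_safe(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [to_json_safe(v) for v in obj.tolist()]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
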