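"""Regulator enrichment of iModulons against a regulatory network.

Each iModulon is tested for overlap with every regulon by the one-sided
hypergeometric tail (probability of drawing at least the observed overlap
when sampling the iModulon's genes from the universe). Benjamini-Hochberg
q-values are computed over the full iModulon x regulator test family, and
each iModulon is named by its most significant regulator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .exceptions import UniverseError
from .structure import IModulon

FDR_DEFAULT = 1e-4


@dataclass
class EnrichmentRecord:
    imodulon_id: str
    regulator: str
    overlap: int
    imodulon_size: int
    regulon_size: int
    universe_size: int
    p_value: float
    q_value: float = float("nan")
    precision: float = 0.0
    recall: float = 0.0
    f1: float = 0.0
    significant: bool = False


def enrich(
    imodulon_members: set[str],
    regulon: set[str],
    universe: set[str],
    imodulon_id: str = "",
    regulator: str = "",
) -> EnrichmentRecord:
    """One-sided hypergeometric overlap test of an iModulon vs one regulon.

    p = P(overlap >= observed) when |iModulon| genes are drawn without
    replacement from a universe containing |regulon| successes. The tail at
    zero observed overlap is exactly 1.
    """
    if not imodulon_members <= universe:
        raise UniverseError("iModulon member outside the gene universe")
    if not regulon <= universe:
        raise UniverseError("regulon gene outside the gene universe")
    n_univ = len(universe)
    n_im = len(imodulon_members)
    n_reg = len(regulon)
    overlap = len(imodulon_members & regulon)
    p = float(hypergeom.sf(overlap - 1, n_univ, n_reg, n_im))
    p = min(p, 1.0)
    precision = overlap / n_im if n_im else 0.0
    recall = overlap / n_reg if n_reg else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if (precision + recall) > 0
        else 0.0
    )
    return EnrichmentRecord(
        imodulon_id=imodulon_id,
        regulator=regulator,
        overlap=overlap,
        imodulon_size=n_im,
        regulon_size=n_reg,
        universe_size=n_univ,
        p_value=p,
        precision=precision,
        recall=recall,
        f1=f1,
    )


def enrich_all(
    imodulons: list[IModulon],
    trn: dict[str, set[str]],
    universe: set[str],
    fdr: float = FDR_DEFAULT,
) -> list[EnrichmentRecord]:
    """Test every iModulon x regulator pair; BH-correct; assign names.

    q-values are Benjamini-Hochberg over the full family of tests (one
    global FDR bar). Each iModulon with at least one significant regulator
    is named by the lowest-q one; ties break toward higher F1, then
    lexicographic regulator name. iModulons with no significant regulator
    stay unnamed.
    """
    if not trn:
        warnings.warn("empty TRN: no iModulon can be named", stacklevel=2)
        return []
    records: list[EnrichmentRecord] = []
    for im in imodulons:
        for reg in sorted(trn):
            records.append(
                enrich(im.members, trn[reg], universe,
                       imodulon_id=im.id, regulator=reg)
            )
    reject, q_values, *_ = multipletests(
        [r.p_value for r in records], alpha=fdr, method="fdr_bh"
    )
    for rec, q, sig in zip(records, q_values, reject):
        rec.q_value = float(q)
        rec.significant = bool(sig)

    by_im: dict[str, list[EnrichmentRecord]] = {}
    for rec in records:
        by_im.setdefault(rec.imodulon_id, []).append(rec)
    for im in imodulons:
        sig = [r for r in by_im.get(im.id, []) if r.significant]
        if sig:
            best = min(sig, key=lambda r: (r.q_value, -r.f1, r.regulator))
            im.name = best.regulator
            im.enrichment = best
        else:
            im.name = None
            im.enrichment = None
    return records
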