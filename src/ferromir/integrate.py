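"""Regulatory-module assembly and set over-representation.

A regulatory module is an (IDE1-containing miRNA, target gene) pair with
antagonistic expression in one organ and contrast: the miRNA promoter must
carry at least one IDE1 element, the target must carry a predicted site at
or below the score cutoff, and the two must be differentially expressed in
the same contrast with opposite signs.  The strict mode requires the
target's own DE call; the relaxed mode only requires an opposite-signed
fold-change, accommodating targets that respond without reaching
significance.

Over-representation uses the one-sided hypergeometric tail with BH
adjustment across terms; annotation databases are user-supplied id sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom

from .diffexp import DESet, bh_adjust
from .motifscan import MotifHit
from .targetpred import TargetHit

__all__ = [
    "RegulatoryModule",
    "EnrichmentResult",
    "build_modules",
    "hypergeom_enrich",
    "modules_to_tsv",
    "modules_to_edges",
]


@dataclass(frozen=True)
class RegulatoryModule:
    """One evidence-backed (miRNA, target) antagonistic pair."""

    mirna_id: str
    target_id: str
    organ: str
    contrast: str
    pattern: str  # "miRNA-up/target-down" or "miRNA-down/target-up"
    mirna_lfc: float
    mirna_p: float
    target_lfc: float
    target_q: float
    ide1_hit: MotifHit
    target_hit: TargetHit


def _organ_of(contrast: str) -> str:
    # contrast format "<trt>_<organ>_vs_<trt>_<organ>"
    return contrast.split("_vs_")[0].rsplit("_", 1)[1]


def build_modules(
    ide1_hits: list[MotifHit],
    de_mirs: dict[str, DESet],
    target_hits: list[TargetHit],
    target_de: dict[str, DESet],
    require_target_significant: bool = True,
) -> list[RegulatoryModule]:
    """Assemble modules from motif, target-site and DE evidence.

    ``ide1_hits`` are promoter scan hits keyed by the miRNA id
    (``promoter_id``); DE sets are keyed by contrast id.  A module is
    emitted per (miRNA, target, contrast) where all four predicates hold;
    the organ is read off the contrast label, so a miRNA's organ
    assignment follows from where it is differentially expressed.  Target
    hits referencing features absent from the DE universe are skipped with
    a warning.  Output order is deterministic: (contrast, miRNA, target).
    """
    ide1_by_mir: dict[str, list[MotifHit]] = {}
    for h in ide1_hits:
        if h.motif_type == "IDE1":
            ide1_by_mir.setdefault(h.promoter_id, []).append(h)

    modules: list[RegulatoryModule] = []
    shared = sorted(set(de_mirs) & set(target_de))
    for contrast in shared:
        dm = de_mirs[contrast]
        dt = target_de[contrast]
        for th in sorted(target_hits, key=lambda t: (t.mirna_id, t.transcript_id)):
            mir, tgt = th.mirna_id, th.transcript_id
            if mir not in ide1_by_mir:
                continue
            if mir not in dm.table.index:
                warnings.warn(f"miRNA {mir!r} absent from DE universe; skipped")
                continue
            if tgt not in dt.table.index:
                warnings.warn(f"target {tgt!r} absent from DE universe; skipped")
                continue
            if mir in dm.up:
                mir_dir = 1
            elif mir in dm.down:
                mir_dir = -1
            else:
                continue
            t_lfc = float(dt.table.loc[tgt, "lfc"])
            if require_target_significant:
                if tgt in dt.up:
                    t_dir = 1
                elif tgt in dt.down:
                    t_dir = -1
                else:
                    continue
            else:
                if t_lfc == 0:
                    continue
                t_dir = 1 if t_lfc > 0 else -1
            if mir_dir == t_dir:
                continue
            best_ide1 = max(ide1_by_mir[mir], key=lambda h: h.total_matches)
            pattern = (
                "miRNA-up/target-down" if mir_dir == 1 else "miRNA-down/target-up"
            )
            modules.append(
                RegulatoryModule(
                    mirna_id=mir,
                    target_id=tgt,
                    organ=_organ_of(contrast),
                    contrast=contrast,
                    pattern=pattern,
                    mirna_lfc=float(dm.table.loc[mir, "lfc"]),
                    mirna_p=float(dm.table.loc[mir, "p"]),
                    target_lfc=t_lfc,
                    target_q=float(dt.table.loc[tgt, "q"]),
                    ide1_hit=best_ide1,
                    target_hit=th,
                )
            )
    modules.sort(key=lambda m: (m.contrast, m.mirna_id, m.target_id))
    return modules


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    universe_size: int
    term_size: int
    sample_size: int
    overlap: int
    p: float
    q: float


def hypergeom_enrich(
    sample: set,
    annotation: dict[str, set],
    universe: set,
) -> list[EnrichmentResult]:
    """One-sided hypergeometric over-representation per term, BH across terms.

    Term sets are intersected with the universe; the sample must be a
    subset of the universe.  Results are sorted by (p, term).
    """
    if not universe:
        raise ValueError("universe must be non-empty")
    if not sample <= universe:
        raise ValueError("sample must be a subset of the universe")
    M = len(universe)
    n = len(sample)
    terms = sorted(annotation)
    ps, rows = [], []
    for term in terms:
        tset = annotation[term] & universe
        k = len(tset & sample)
        p = float(hypergeom.sf(k - 1, M, len(tset), n))
        ps.append(min(1.0, p))
        rows.append((term, len(tset), k))
    qs = bh_adjust(np.array(ps)) if ps else np.array([])
    out = [
        EnrichmentResult(term, M, tsize, n, k, p, float(q))
        for (term, tsize, k), p, q in zip(rows, ps, qs)
    ]
    out.sort(key=lambda r: (r.p, r.term))
    return out


def modules_to_tsv(modules: list[RegulatoryModule]) -> str:
    rows = [
        "mirna\ttarget\torgan\tcontrast\tpattern\tmirna_lfc\tmirna_p\t"
        "target_lfc\ttarget_q\tide1_location\ttarget_score"
    ]
    for m in modules:
        rows.append(
            f"{m.mirna_id}\t{m.target_id}\t{m.organ}\t{m.contrast}\t{m.pattern}\t"
            f"{m.mirna_lfc:.4g}\t{m.mirna_p:.4g}\t{m.target_lfc:.4g}\t"
            f"{m.target_q:.4g}\t{m.ide1_hit.upstream_start}/"
            f"{m.ide1_hit.upstream_end}\t{m.target_hit.score:g}"
        )
    return "\n".join(rows) + "\n"


def modules_to_edges(modules: list[RegulatoryModule]) -> list[tuple[str, str]]:
    """Deduplicated miRNA -> target edge list for network tools."""
    return sorted({(m.mirna_id, m.target_id) for m in modules})
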