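"""Degenerate matching of iron-deficiency-responsive promoter elements.

IDE1 and IDE2 are conserved cis-elements that confer Fe-deficiency-inducible
transcription in plant promoters.  IDE1 is modeled as two consecutive 9-bp
modules (18 bp); IDE2 as three 9-bp modules (27 bp) whose middle module is
the functional core.  A candidate window matches when every module retains
enough identical bases:

* IDE1: each of the two modules must match the consensus at >= 6 of 9
  positions (66.7 %).
* IDE2: the core must match >= 6/9; the whole element must keep at least
  ``ide2_min_total`` (default 14) of its 27 positions; each flanking module
  must satisfy a 6/9 requirement whose default ("positional") reading pins
  the six core-proximal positions of the flank — substitutions in the three
  core-distal positions of a flank never by themselves cause rejection.  A
  count-based reading (any 6 of the 9 flank positions) is available via
  ``flank_rule="count"``.

Candidates may be up to ``max_gaps`` bases shorter than the consensus; each
gap is a deletion relative to the consensus and counts as a mismatch in the
module it falls in.  A candidate is accepted when ANY gap placement meets
the module criteria; the reported placement is the accepting one with the
most total matches (ties broken by the leftmost gap).

Hits are reported in the upstream-offset convention used for promoter
elements: offsets are negative, 1-based and inclusive, with -1 denoting the
base immediately upstream of the anchor (TSS or pre-miRNA 5' end); the
anchor is always the 3' end of the supplied sequence.  A 0-based local
interval ``[s, e)`` in a window of length ``L`` maps to upstream offsets
``-(L - s)`` through ``-(L - e + 1)``.

The shipped consensus sequences are externally sourced defaults (the
elements were characterized in barley promoters) and are plain constructor
arguments — override them for any other element model.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

__all__ = [
    "IDE1_CONSENSUS",
    "IDE2_CONSENSUS",
    "MotifModel",
    "ModuleMatch",
    "MotifHit",
    "ide1_model",
    "ide2_model",
    "match_module",
    "match_ide1",
    "match_ide2",
    "scan_promoter",
    "scan_promoters",
    "hits_to_bed",
    "hits_to_table",
    "local_to_upstream",
    "upstream_to_local",
    "revcomp",
    "module_threshold_percent",
]

#: Default IDE1 consensus (two 9-bp modules). Externally sourced default.
IDE1_CONSENSUS = "ATCAAGCATGCTTCTTGC"
#: Default IDE2 consensus (three 9-bp modules, middle = core). Externally
#: sourced default.
IDE2_CONSENSUS = "TTGAACGGCAAGTTTCACGCTGTCACT"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGT(N) sequence."""
    return seq.translate(_COMPLEMENT)[::-1]


def module_threshold_percent(min_matches: int = 6, module_length: int = 9) -> float:
    """Per-module identity threshold expressed as a percentage (one decimal).

    The 6-of-9 criterion used for every 9-bp module corresponds to 66.7 %.
    """
    return round(100.0 * min_matches / module_length, 1)


@dataclass(frozen=True)
class MotifModel:
    """An IDE-style modular consensus plus its hierarchical match thresholds."""

    motif_type: Literal["IDE1", "IDE2"]
    modules: tuple[str, ...]
    core_index: int | None = None
    min_matches_per_module: int = 6
    ide2_min_total: int = 14
    max_gaps: int = 1
    window: int = 2000
    flank_rule: Literal["positional", "count"] = "positional"
    both_strands: bool = True

    def __post_init__(self) -> None:
        if any(len(m) != 9 for m in self.modules):
            raise ValueError("every consensus module must be 9 bp")
        if self.motif_type == "IDE1":
            if len(self.modules) != 2:
                raise ValueError("IDE1 has exactly 2 modules")
            if self.core_index is not None:
                raise ValueError("IDE1 has no core module")
        elif self.motif_type == "IDE2":
            if len(self.modules) != 3:
                raise ValueError("IDE2 has exactly 3 modules")
            if self.core_index != 1:
                raise ValueError("IDE2 core must be the middle module")
        else:
            raise ValueError(f"unknown motif_type {self.motif_type!r}")
        if not 0 <= self.min_matches_per_module <= 9:
            raise ValueError("min_matches_per_module must be in [0, 9]")
        if self.ide2_min_total > 9 * len(self.modules):
            raise ValueError("ide2_min_total exceeds motif length")
        if self.max_gaps < 0:
            raise ValueError("max_gaps must be >= 0")

    @property
    def consensus(self) -> str:
        return "".join(self.modules)

    @property
    def length(self) -> int:
        return 9 * len(self.modules)


def ide1_model(consensus: str = IDE1_CONSENSUS, **kwargs) -> MotifModel:
    """Build the two-module IDE1 model from an 18-bp consensus."""
    if len(consensus) != 18:
        raise ValueError("IDE1 consensus must be 18 bp")
    return MotifModel("IDE1", (consensus[:9], consensus[9:]), **kwargs)


def ide2_model(consensus: str = IDE2_CONSENSUS, **kwargs) -> MotifModel:
    """Build the three-module IDE2 model (middle module = core) from 27 bp."""
    if len(consensus) != 27:
        raise ValueError("IDE2 consensus must be 27 bp")
    return MotifModel(
        "IDE2", (consensus[:9], consensus[9:18], consensus[18:]), core_index=1, **kwargs
    )


@dataclass(frozen=True)
class ModuleMatch:
    """Result of aligning a candidate against a modular consensus."""

    per_module_matches: tuple[int, ...]
    total_matches: int
    gap_positions: tuple[int, ...]  # 0-based consensus positions deleted

    @property
    def gap_count(self) -> int:
        return len(self.gap_positions)


def _check_alphabet(seq: str, allow_n: bool = False) -> None:
    allowed = set("ACGTN" if allow_n else "ACGT")
    bad = set(seq) - allowed
    if bad:
        raise ValueError(f"non-ACGT characters in sequence: {sorted(bad)}")


def match_module(candidate: str, consensus: str) -> int:
    """Count identical positions between a candidate 9-mer and a consensus 9-mer."""
    if len(candidate) != 9 or len(consensus) != 9:
        raise ValueError("match_module requires two 9-mers")
    _check_alphabet(candidate)
    _check_alphabet(consensus)
    return sum(a == b for a, b in zip(candidate, consensus))


def _placement_matches(
    candidate: str, consensus: str, gaps: tuple[int, ...]
) -> tuple[int, ...]:
    """Per-module match counts for one gap placement.

    ``gaps`` are consensus positions left unpaired (deletions in the
    candidate); a gap contributes zero matches to its module.
    """
    n_modules = len(consensus) // 9
    counts = [0] * n_modules
    ci = 0
    gapset = set(gaps)
    for pos, base in enumerate(consensus):
        if pos in gapset:
            continue
        if candidate[ci] == base:
            counts[pos // 9] += 1
        ci += 1
    return tuple(counts)


def _accepts(model: MotifModel, counts: Sequence[int]) -> bool:
    if model.motif_type == "IDE1":
        return all(c >= model.min_matches_per_module for c in counts)
    # IDE2 hierarchy
    core = counts[model.core_index]
    if core < model.min_matches_per_module:
        return False
    if sum(counts) < model.ide2_min_total:
        return False
    if model.flank_rule == "count":
        return all(
            counts[i] >= model.min_matches_per_module
            for i in (0, 2)
        )
    return True  # positional flank rule handled per-position, see below


def _positional_flank_ok(
    candidate: str, consensus: str, gaps: tuple[int, ...]
) -> bool:
    """Positional flank reading: the 6 core-proximal positions of each flank
    must match exactly (left flank: consensus positions 3-8; right flank:
    18-23).  A gap inside those positions is a mismatch."""
    required = set(range(3, 9)) | set(range(18, 24))
    gapset = set(gaps)
    ci = 0
    for pos, base in enumerate(consensus):
        if pos in gapset:
            if pos in required:
                return False
            continue
        if pos in required and candidate[ci] != base:
            return False
        ci += 1
    return True


def _match_modular(candidate: str, model: MotifModel) -> ModuleMatch | None:
    """Shared engine for match_ide1/match_ide2.

    Accepts iff any gap placement satisfies the model's criteria; among
    accepting placements the one with maximal total matches wins, ties
    broken by the leftmost gap tuple.
    """
    consensus = model.consensus
    n_gaps = len(consensus) - len(candidate)
    if not 0 <= n_gaps <= model.max_gaps:
        raise ValueError(
            f"candidate length {len(candidate)} outside "
            f"[{len(consensus) - model.max_gaps}, {len(consensus)}]"
        )
    _check_alphabet(candidate)
    best: tuple[int, tuple[int, ...], tuple[int, ...]] | None = None
    for gaps in itertools.combinations(range(len(consensus)), n_gaps):
        counts = _placement_matches(candidate, consensus, gaps)
        if not _accepts(model, counts):
            continue
        if (
            model.motif_type == "IDE2"
            and model.flank_rule == "positional"
            and not _positional_flank_ok(candidate, consensus, gaps)
        ):
            continue
        total = sum(counts)
        # maximize total; tie -> lexicographically smallest (leftmost) gaps
        key = (total, tuple(-g for g in gaps))
        if best is None or key > (best[0], tuple(-g for g in best[2])):
            best = (total, counts, gaps)
    if best is None:
        return None
    total, counts, gaps = best
    return ModuleMatch(counts, total, gaps)


def match_ide1(candidate: str, model: MotifModel | None = None) -> ModuleMatch | None:
    """Match an 18-bp (or gapped 17-bp) candidate against the IDE1 model.

    Returns a :class:`ModuleMatch` when both modules reach the 6/9
    threshold, ``None`` on a failed match; a candidate whose length falls
    outside ``[18 - max_gaps, 18]`` raises ``ValueError`` (a distinct signal
    from a failed match).
    """
    model = model or ide1_model()
    if model.motif_type != "IDE1":
        raise ValueError("model.motif_type must be IDE1")
    return _match_modular(candidate, model)


def match_ide2(candidate: str, model: MotifModel | None = None) -> ModuleMatch | None:
    """Match a 27-bp (or gapped) candidate against the hierarchical IDE2 model."""
    model = model or ide2_model()
    if model.motif_type != "IDE2":
        raise ValueError("model.motif_type must be IDE2")
    return _match_modular(candidate, model)


@dataclass(frozen=True)
class MotifHit:
    """One accepted motif occurrence in a promoter window."""

    promoter_id: str
    motif_type: str
    upstream_start: int  # negative, 1-based inclusive
    upstream_end: int  # negative, 1-based inclusive; start < end <= -1
    strand: str
    per_module_matches: tuple[int, ...]
    gap_count: int
    matched_sequence: str
    total_matches: int
    local_start: int = field(default=0, repr=False)  # 0-based in scanned window
    local_end: int = field(default=0, repr=False)

    def __post_init__(self) -> None:
        if not self.upstream_start < self.upstream_end <= -1:
            raise ValueError("upstream offsets must satisfy start < end <= -1")


def local_to_upstream(s: int, e: int, window_length: int) -> tuple[int, int]:
    """Map a 0-based local interval ``[s, e)`` to upstream offsets.

    In a window of length ``L`` the interval maps to the inclusive offsets
    ``(-(L - s), -(L - e + 1))``; e.g. ``[1645, 1663)`` in 2000 bp is
    ``(-355, -338)``.
    """
    return -(window_length - s), -(window_length - e + 1)


def upstream_to_local(start: int, end: int, window_length: int) -> tuple[int, int]:
    """Inverse of :func:`local_to_upstream` (returns a 0-based ``[s, e)``)."""
    return window_length + start, window_length + end + 1


def _matcher_for(model: MotifModel):
    return match_ide1 if model.motif_type == "IDE1" else match_ide2


def scan_promoter(
    promoter: str,
    model: MotifModel,
    promoter_id: str = "promoter",
) -> list[MotifHit]:
    """Exhaustively scan a promoter window for the model's element.

    Only the window-proximal suffix (last ``model.window`` bp, the region
    nearest the anchor) is scanned.  Every start position, both strands
    (unless ``model.both_strands`` is False) and every allowed gap count are
    tested; overlapping accepted windows are collapsed to the single best
    hit (maximal total matches, ties to fewer gaps, then most upstream).
    Windows containing N never match.
    """
    promoter = promoter.upper()
    _check_alphabet(promoter, allow_n=True)
    seq = promoter[-model.window :] if len(promoter) > model.window else promoter
    L = len(seq)
    matcher = _matcher_for(model)
    strands = ("+", "-") if model.both_strands else ("+",)
    raw: list[MotifHit] = []
    for strand in strands:
        s2 = seq if strand == "+" else revcomp(seq)
        for n_gaps in range(model.max_gaps + 1):
            clen = model.length - n_gaps
            for start in range(L - clen + 1):
                cand = s2[start : start + clen]
                if "N" in cand:
                    continue
                m = matcher(cand, model)
                if m is None:
                    continue
                if strand == "+":
                    fs, fe = start, start + clen
                else:
                    fs, fe = L - (start + clen), L - start
                us, ue = local_to_upstream(fs, fe, L)
                raw.append(
                    MotifHit(
                        promoter_id=promoter_id,
                        motif_type=model.motif_type,
                        upstream_start=us,
                        upstream_end=ue,
                        strand=strand,
                        per_module_matches=m.per_module_matches,
                        gap_count=m.gap_count,
                        matched_sequence=cand,
                        total_matches=m.total_matches,
                        local_start=fs,
                        local_end=fe,
                    )
                )
    return _collapse_overlaps(raw)


def _collapse_overlaps(hits: list[MotifHit]) -> list[MotifHit]:
    """Greedy non-overlap selection per strand: best total matches, then
    fewer gaps, then most upstream (smallest local start).  The strands are
    distinct match spaces, so a plus-strand hit never suppresses an
    overlapping minus-strand hit or vice versa."""
    ordered = sorted(
        hits, key=lambda h: (-h.total_matches, h.gap_count, h.local_start)
    )
    kept: list[MotifHit] = []
    for h in ordered:
        if all(
            h.strand != k.strand
            or h.local_end <= k.local_start
            or h.local_start >= k.local_end
            for k in kept
        ):
            kept.append(h)
    kept.sort(key=lambda h: (h.local_start, h.strand))
    return kept


def scan_promoters(
    promoters: dict[str, str], models: Iterable[MotifModel]
) -> list[MotifHit]:
    """Scan a promoter set (id -> sequence) against one or more motif models."""
    hits: list[MotifHit] = []
    for pid, seq in promoters.items():
        for model in models:
            hits.extend(scan_promoter(seq, model, promoter_id=pid))
    return hits


def hits_to_bed(hits: Iterable[MotifHit]) -> str:
    """BED6 text (0-based half-open promoter-local coordinates; score =
    total matches, name = motif type)."""
    lines = [
        "\t".join(
            [
                h.promoter_id,
                str(h.local_start),
                str(h.local_end),
                h.motif_type,
                str(h.total_matches),
                h.strand,
            ]
        )
        for h in hits
    ]
    return "\n".join(lines) + ("\n" if lines else "")


def hits_to_table(hits: Iterable[MotifHit], table1_style: bool = False) -> str:
    """TSV of hits with upstream offsets (columns: promoter, motif, sequence,
    location, strand, matches).

    ``table1_style=True`` reproduces the published end-offset convention in
    which the printed span covers motif-length + 1 positions
    (end = start + motif length).
    """
    rows = ["promoter\tmotif\tsequence\tlocation\tstrand\tmatches"]
    for h in hits:
        end = h.upstream_end
        if table1_style:
            end = h.upstream_start + (h.local_end - h.local_start)
        rows.append(
            "\t".join(
                [
                    h.promoter_id,
                    h.motif_type,
                    h.matched_sequence,
                    f"{h.upstream_start}/{end}",
                    h.strand,
                    str(h.total_matches),
                ]
            )
        )
    return "\n".join(rows) + "\n"
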