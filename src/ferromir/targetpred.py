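"""Plant miRNA target-site prediction with a penalty score.

A miRNA (5'->3') pairs antiparallel with a transcript site; each alignment
column is one of Watson-Crick (WC, penalty 0), G:U wobble (0.5), mismatch
(MM, 1.0) or gap (2.0).  Penalties double inside the weight region,
positions 2-13 from the miRNA 5' end, reflecting the functional importance
of the 5' seed-proximal region for cleavage-guided plant miRNAs.  A gap's
position is the 1-based miRNA position it interrupts: a deleted site base
takes the position of the unpaired miRNA base; an inserted site base takes
the position of the next miRNA base.  Lower scores mean better
complementarity; sites at or below the cutoff (default 2.5, inclusive) are
retained.

U and T are treated as equivalent on input; the internal alphabet is RNA.
The search is exhaustive over all antiparallel windows with up to
``max_gaps`` of length slack; for ``max_gaps <= 1`` an exact vectorized
enumeration (gapless + every single-gap split) is used, larger gap budgets
fall back to a banded dynamic program.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Literal

import numpy as np

__all__ = [
    "PENALTIES",
    "WEIGHT_REGION",
    "DuplexAlignment",
    "TargetHit",
    "pair_state",
    "penalty_score",
    "find_best_site",
    "predict_targets",
]

#: Per-column penalties by pairing state.
PENALTIES = {"WC": 0.0, "GU": 0.5, "MM": 1.0, "GAP": 2.0}
#: 1-based inclusive miRNA positions where penalties double.
WEIGHT_REGION = (2, 13)

_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_GU = {("G", "U"), ("U", "G")}


def _to_rna(seq: str) -> str:
    seq = seq.upper().replace("T", "U")
    bad = set(seq) - set("ACGU")
    if bad:
        raise ValueError(f"non-ACGU/ACGT characters: {sorted(bad)}")
    return seq


def pair_state(mirna_base: str, site_base: str) -> str:
    """Pairing state of one alignment column (bases in RNA alphabet)."""
    pair = (mirna_base, site_base)
    if pair in _WC:
        return "WC"
    if pair in _GU:
        return "GU"
    return "MM"


@dataclass(frozen=True)
class DuplexAlignment:
    """A miRNA:site duplex as per-position pairing states.

    ``states`` runs 1..n from the miRNA 5' end; gap columns carry the
    miRNA position they interrupt.  ``mirna`` and ``site`` are RNA-alphabet;
    the site is stored 5'->3' as it appears on the transcript.
    """

    mirna: str
    site: str
    states: tuple[str, ...]
    positions: tuple[int, ...]  # 1-based miRNA position per column

    def __post_init__(self) -> None:
        if len(self.states) != len(self.positions):
            raise ValueError("states and positions must align")
        if any(s not in PENALTIES for s in self.states):
            raise ValueError("unknown pairing state")

    @property
    def gap_count(self) -> int:
        return sum(s == "GAP" for s in self.states)

    def pairing_string(self) -> str:
        sym = {"WC": "|", "GU": "o", "MM": ".", "GAP": "-"}
        return "".join(sym[s] for s in self.states)


def penalty_score(
    duplex: DuplexAlignment,
    weight_region: tuple[int, int] = WEIGHT_REGION,
    penalties: dict[str, float] = PENALTIES,
) -> float:
    """Sum of per-column penalties, doubled inside the weight region."""
    lo, hi = weight_region
    total = 0.0
    for state, pos in zip(duplex.states, duplex.positions):
        w = 2.0 if lo <= pos <= hi else 1.0
        total += w * penalties[state]
    return total


@dataclass(frozen=True)
class TargetHit:
    """One predicted target site on a transcript (1-based inclusive coords)."""

    mirna_id: str
    transcript_id: str
    start: int
    end: int
    score: float
    alignment: DuplexAlignment

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError("score must be >= 0")


def _weights(n: int, weight_region: tuple[int, int]) -> np.ndarray:
    lo, hi = weight_region
    w = np.ones(n)
    w[lo - 1 : hi] = 2.0
    return w


_ENC = {"A": 0, "C": 1, "G": 2, "U": 3}


@lru_cache(maxsize=None)
def _pen_table() -> np.ndarray:
    t = np.full((4, 4), PENALTIES["MM"])
    for (a, b), st in [(p, "WC") for p in _WC] + [(p, "GU") for p in _GU]:
        t[_ENC[a], _ENC[b]] = PENALTIES[st]
    return t


_BIG = 1e9


def _best_site_enum(
    m: str, t: str, max_gaps: int, weight_region: tuple[int, int]
) -> tuple[float, int, int, list[tuple[str, int]]] | None:
    """Exact search for max_gaps <= 1 via vectorized enumeration.

    All gapless offsets plus every single-gap split (a deleted or inserted
    site base at each miRNA position) are scored with prefix/suffix sums of
    the per-column penalty matrix.  Returns (score, start0, end0, columns)
    where columns are (state, miRNA position) and [start0, end0) are
    0-based transcript coordinates; None when the transcript is too short.
    """
    n = len(m)
    L = len(t)
    r = t[::-1]  # transcript read 3'->5'; pairs the miRNA 5'->3'
    if L < n - max_gaps:
        return None
    menc = np.array([_ENC[b] for b in m])
    # pad with a sentinel base (index 4, infinite penalty) so out-of-range
    # alignments price themselves out
    rpad = np.full(L + n + 1, 4, dtype=int)
    rpad[1 : L + 1] = [_ENC[b] for b in r]
    pen = np.full((4, 5), _BIG)
    pen[:, :4] = _pen_table()
    w = _weights(n, weight_region)
    gap_w = PENALTIES["GAP"] * _weights(n, weight_region)  # gap at position g+1

    # row j <-> offset o = j - 1: P[j, i] = weighted penalty of miRNA i
    # paired with r[o + i]
    from numpy.lib.stride_tricks import sliding_window_view

    SW = sliding_window_view(rpad, n)  # rows j = 0 .. L + 1
    P = pen[menc[None, :], SW] * w[None, :]
    T = P.sum(axis=1)
    C = np.concatenate([np.zeros((P.shape[0], 1)), np.cumsum(P, axis=1)], axis=1)
    S = T[:, None] - C  # S[j, g] = sum over i >= g

    best: tuple[float, int, int, tuple] | None = None

    def consider(score, o, site_len, how):
        nonlocal best
        if score >= _BIG:
            return
        start0 = L - (o + site_len)
        end0 = L - o
        key = (round(score, 9), start0, end0, how)
        if best is None or key < (round(best[0], 9), best[1], best[2], best[3]):
            best = (score, start0, end0, how)

    if L >= n:
        scores = T[1 : L - n + 2]  # offsets 0 .. L - n
        o = int(np.argmin(scores))
        # tie-break 5'-most on transcript = largest offset into r
        ties = np.flatnonzero(np.isclose(scores, scores[o]))
        o = int(ties[-1])
        consider(float(scores[o]), o, n, ("gapless", o))

    if max_gaps >= 1:
        # deleted site base: miRNA g unpaired; miRNA[i<g] pairs r[o+i]
        # (row o+1), miRNA[i>g] pairs r[o+i-1] (row o)
        if L >= n - 1:
            j = np.arange(L - n + 2)  # site starts o' = j
            G = np.arange(n)
            Del = C[np.ix_(j + 1, G)] + gap_w[None, :] + S[np.ix_(j, G + 1)]
            o_, g_ = _argmin_tie(Del)
            consider(float(Del[o_, g_]), int(o_), n - 1, ("sitedel", int(o_), int(g_)))
        # inserted site base between miRNA g-1 and g: prefix row o+1,
        # suffix pairs r[o+i+1] (row o+2); internal insertions only
        if L >= n + 1:
            j = np.arange(L - n)  # site starts o' = j, length n + 1
            G = np.arange(1, n)
            Ins = C[np.ix_(j + 1, G)] + gap_w[None, G] + S[np.ix_(j + 2, G)]
            o_, g_ = _argmin_tie(Ins)
            consider(
                float(Ins[o_, g_]), int(o_), n + 1, ("siteins", int(o_), int(G[g_]))
            )
    if best is None or best[0] >= _BIG:
        return None
    score, start0, end0, how = best
    cols = _build_columns(m, r, how, n)
    return score, start0, end0, cols


def _argmin_tie(M: np.ndarray) -> tuple[int, int]:
    """(row, col) of the minimum; ties -> largest row (5'-most site), then
    smallest col (leftmost gap)."""
    flat = np.isclose(M, M.min())
    rows = np.flatnonzero(flat.any(axis=1))
    row = int(rows[-1])
    col = int(np.flatnonzero(flat[row])[0])
    return row, col


def _build_columns(m: str, r: str, how: tuple, n: int) -> list[tuple[str, int]]:
    kind = how[0]
    cols: list[tuple[str, int]] = []
    if kind == "gapless":
        o = how[1]
        for i in range(n):
            cols.append((pair_state(m[i], r[o + i]), i + 1))
    elif kind == "sitedel":
        _, o, g = how
        for i in range(g):
            cols.append((pair_state(m[i], r[o + i]), i + 1))
        cols.append(("GAP", g + 1))
        for i in range(g + 1, n):
            cols.append((pair_state(m[i], r[o + i - 1]), i + 1))
    elif kind == "siteins":
        _, o, g = how
        for i in range(g):
            cols.append((pair_state(m[i], r[o + i]), i + 1))
        cols.append(("GAP", g + 1))
        for i in range(g, n):
            cols.append((pair_state(m[i], r[o + i + 1]), i + 1))
    return cols


def _best_site_dp(
    m: str, t: str, max_gaps: int, weight_region: tuple[int, int]
) -> tuple[float, int, int, list[tuple[str, int]]] | None:
    """Exhaustive recursive alignment for arbitrary gap budgets (small inputs)."""
    n = len(m)
    L = len(t)
    r = t[::-1]
    w = _weights(n + 1, weight_region)
    pen = PENALTIES
    best: list = [None]

    def pair_pen(i: int, p: int) -> float:
        return w[i] * pen[pair_state(m[i], r[p])]

    def rec(i, p, gaps, score, cols, o):
        if best[0] is not None and score >= best[0][0] + 1e-12:
            pass
        if i == n:
            start0 = L - p
            end0 = L - o
            key = (round(score, 9), start0, end0)
            if best[0] is None or key < (round(best[0][0], 9), best[0][1], best[0][2]):
                best[0] = (score, start0, end0, list(cols))
            return
        # pair
        if p < L:
            cols.append((pair_state(m[i], r[p]), i + 1))
            rec(i + 1, p + 1, gaps, score + pair_pen(i, p), cols, o)
            cols.pop()
        # site deletion (miRNA base unpaired)
        if gaps < max_gaps:
            cols.append(("GAP", i + 1))
            rec(i + 1, p, gaps + 1, score + w[i] * pen["GAP"], cols, o)
            cols.pop()
        # site insertion (site base unpaired), internal only
        if gaps < max_gaps and 0 < i < n and p < L:
            cols.append(("GAP", i + 1))
            rec(i, p + 1, gaps + 1, score + w[i] * pen["GAP"], cols, o)
            cols.pop()

    for o in range(L + 1):
        rec(0, o, 0, 0.0, [], o)
    return best[0]


def find_best_site(
    mirna: str,
    transcript: str,
    max_gaps: int = 1,
    cutoff: float | None = 2.5,
    weight_region: tuple[int, int] = WEIGHT_REGION,
) -> TargetHit | None:
    """Minimal-penalty antiparallel site of a miRNA on a transcript.

    Scans every window with up to ``max_gaps`` length slack; ties go to
    the 5'-most site on the transcript.  Returns None when the minimal
    score exceeds ``cutoff`` (pass ``cutoff=None`` to always return the
    best site).  Coordinates are 1-based inclusive on the transcript.
    """
    m = _to_rna(mirna)
    t = _to_rna(transcript)
    if len(t) < len(m) - max_gaps:
        raise ValueError("transcript shorter than miRNA minus gap allowance")
    if max_gaps <= 1:
        res = _best_site_enum(m, t, max_gaps, weight_region)
    else:
        res = _best_site_dp(m, t, max_gaps, weight_region)
    if res is None:
        return None
    score, start0, end0, cols = res
    if cutoff is not None and score > cutoff:
        return None
    site = t[start0:end0]
    dup = DuplexAlignment(
        mirna=m,
        site=site,
        states=tuple(s for s, _ in cols),
        positions=tuple(p for _, p in cols),
    )
    return TargetHit(
        mirna_id="miRNA",
        transcript_id="transcript",
        start=start0 + 1,
        end=end0,
        score=score,
        alignment=dup,
    )


def predict_targets(
    mirnas: dict[str, str],
    transcripts: dict[str, str],
    cutoff: float = 2.5,
    max_gaps: int = 1,
) -> list[TargetHit]:
    """All (miRNA, transcript) best sites with score <= cutoff.

    Deterministic ordering by (miRNA id, transcript id, site start).
    """
    hits: list[TargetHit] = []
    for mid in sorted(mirnas):
        for tid in sorted(transcripts):
            h = find_best_site(mirnas[mid], transcripts[tid], max_gaps, cutoff)
            if h is not None:
                hits.append(
                    TargetHit(mid, tid, h.start, h.end, h.score, h.alignment)
                )
    hits.sort(key=lambda h: (h.mirna_id, h.transcript_id, h.start))
    return hits


def hits_to_tsv(hits: Iterable[TargetHit]) -> str:
    """TSV export: miRNA, transcript, start, end, score, pairing string."""
    rows = ["mirna\ttranscript\tstart\tend\tscore\tpairing"]
    for h in hits:
        rows.append(
            f"{h.mirna_id}\t{h.transcript_id}\t{h.start}\t{h.end}\t"
            f"{h.score:g}\t{h.alignment.pairing_string()}"
        )
    return "\n".join(rows) + "\n"
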