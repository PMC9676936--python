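"""Putative G-quadruplex (QGRS) motif detection and variant impact.

A quadruplex-forming G-rich sequence is four G-tracts of equal length
``x >= 2`` separated by three loops: ``G{x} N{y1} G{x} N{y2} G{x} N{y3}
G{x}``, all within a bounded window.  Every candidate decomposition is
enumerated and scored — shorter motifs with more even (shorter) loops and
longer tracts score higher — then non-overlapping motifs are selected
greedily by descending score.  Scanning is sense-strand only by default,
matching how promoter/intron quadruplexes are reported for this locus.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .synthgen import AlleleEdit, reverse_complement

__all__ = ["G4Params", "G4Motif", "find_g4", "variant_g4_report",
           "write_bed"]


@dataclass
class G4Params:
    min_tract: int = 2
    max_len: int = 30
    max_loop: int | None = None  # default: whatever fits in max_len
    score_c: float = 1.0  # weight of the loop-length term

    def __post_init__(self) -> None:
        if self.min_tract < 2:
            raise ValueError("G-tracts need at least two Gs")
        if self.max_len < 4 * self.min_tract:
            raise ValueError("max_len cannot fit four minimal tracts")


@dataclass(frozen=True)
class G4Motif:
    start: int  # 1-based inclusive
    end: int
    sequence: str
    tract_len: int
    loops: tuple[int, int, int]
    score: float

    def matches_pattern(self) -> bool:
        """Re-check the G4 decomposition this motif claims."""
        s, x = self.sequence, self.tract_len
        pos = 0
        for i in range(4):
            if s[pos:pos + x] != "G" * x:
                return False
            pos += x
            if i < 3:
                pos += self.loops[i]
        return pos == len(s)


def _g_runs(seq: str) -> np.ndarray:
    """run[i] = length of the G-run starting at i (0 if seq[i] != G)."""
    n = len(seq)
    run = np.zeros(n + 1, dtype=np.int32)
    for i in range(n - 1, -1, -1):
        run[i] = run[i + 1] + 1 if seq[i] == "G" else 0
    return run[:n]


def _score(x: int, loops: tuple[int, int, int], p: G4Params) -> float:
    return p.score_c * (p.max_len - sum(loops) / 3.0) \
        + 2.0 * (x - p.min_tract)


def _candidates(seq: str, p: G4Params):
    """Enumerate every (start, end, x, loops) decomposition within limits."""
    run = _g_runs(seq)
    n = len(seq)
    max_loop = p.max_loop if p.max_loop is not None \
        else p.max_len - 4 * p.min_tract
    for i in range(n):
        if run[i] < p.min_tract:
            continue
        x_hi = min(int(run[i]), p.max_len // 4)
        for x in range(p.min_tract, x_hi + 1):
            budget = p.max_len - 4 * x  # total loop budget
            if budget < 0:
                continue
            t2_base = i + x
            for y1 in range(0, min(max_loop, budget) + 1):
                t2 = t2_base + y1
                if t2 + 3 * x > n or run[t2] < x:
                    continue
                for y2 in range(0, min(max_loop, budget - y1) + 1):
                    t3 = t2 + x + y2
                    if t3 + 2 * x > n or run[t3] < x:
                        continue
                    for y3 in range(0, min(max_loop, budget - y1 - y2) + 1):
                        t4 = t3 + x + y3
                        if t4 + x > n or run[t4] < x:
                            continue
                        end = t4 + x  # exclusive
                        yield (i, end, x, (y1, y2, y3))


def find_g4(sequence: str, params: G4Params | None = None,
            scan_reverse: bool = False) -> list[G4Motif]:
    """Non-overlapping G4 motifs, best-scoring first.

    All pattern decompositions within ``max_len`` are enumerated and scored
    with ``score = c * (max_len - mean loop length) + 2 * (tract_len -
    min_tract)``; motifs are then selected greedily by descending score,
    ties by leftmost start, then longest tract, then shortest span.  With
    ``scan_reverse`` the reverse strand is scanned too (coordinates stay on
    the forward sequence); the default is sense-strand only.
    """
    p = params or G4Params()
    seq = sequence.upper()
    cands = [(s, e, x, loops, _score(x, loops, p))
             for s, e, x, loops in _candidates(seq, p)]
    if scan_reverse:
        rc = reverse_complement(seq)
        n = len(seq)
        for s, e, x, loops, sc in [(s, e, x, lo, _score(x, lo, p))
                                   for s, e, x, lo in _candidates(rc, p)]:
            cands.append((n - e, n - s, x, loops, sc))
    cands.sort(key=lambda c: (-c[4], c[0], -c[2], c[1]))
    chosen: list[G4Motif] = []
    taken: list[tuple[int, int]] = []
    for s, e, x, loops, sc in cands:
        if any(s < te and ts < e for ts, te in taken):
            continue
        taken.append((s, e))
        chosen.append(G4Motif(start=s + 1, end=e, sequence=seq[s:e],
                              tract_len=x, loops=loops, score=sc))
    return chosen


def _shift(position: int, variants: Sequence[AlleleEdit],
           upto: AlleleEdit) -> int:
    """Coordinate shift accumulated by variants left of ``position``."""
    shift = 0
    for v in variants:
        if v is upto:
            continue
        if v.span()[1] < position:
            shift += v.signed_length
    return shift


def variant_g4_report(motifs_ref: Sequence[G4Motif],
                      motifs_alt: Sequence[G4Motif],
                      variants: Sequence[AlleleEdit]) -> pd.DataFrame:
    """Per-variant impact on G4 motifs between a reference and its edited
    sequence.

    Each variant is annotated with the reference motif it overlaps (if
    any), the corresponding motif on the edited sequence (matched by
    shifted coordinates), and the score delta.  Impact classes: ``none``
    (no motif involved), ``score_change``, ``lost``, ``gained``,
    ``unchanged``.
    """
    rows = []
    for v in variants:
        vs, ve = v.span()
        ref_hit = next((m for m in motifs_ref
                        if m.start <= ve and vs <= m.end), None)
        shift = _shift(vs, variants, v)
        if ref_hit is not None:
            a, b = ref_hit.start + shift, ref_hit.end + shift + v.signed_length
            alt_hit = next((m for m in motifs_alt
                            if m.start <= b and a <= m.end), None)
        else:
            a, b = vs + shift, ve + shift + max(v.signed_length, 0)
            alt_hit = next((m for m in motifs_alt
                            if m.start <= b and a <= m.end), None)
        if ref_hit is None and alt_hit is None:
            impact, delta = "none", 0.0
        elif ref_hit is None:
            impact, delta = "gained", alt_hit.score
        elif alt_hit is None:
            impact, delta = "lost", -ref_hit.score
        else:
            delta = alt_hit.score - ref_hit.score
            impact = "score_change" if delta != 0 else "unchanged"
        rows.append({
            "kind": v.kind, "position": v.position, "length": v.length,
            "ref_motif_start": ref_hit.start if ref_hit else pd.NA,
            "ref_motif_score": ref_hit.score if ref_hit else pd.NA,
            "alt_motif_start": alt_hit.start if alt_hit else pd.NA,
            "alt_motif_score": alt_hit.score if alt_hit else pd.NA,
            "score_delta": delta, "impact": impact,
        })
    return pd.DataFrame(rows)


def write_bed(motifs: Sequence[G4Motif], path, name: str = "seq") -> None:
    """Motifs as BED (0-based half-open, converted at this boundary)."""
    with open(path, "w") as fh:
        for m in sorted(motifs, key=lambda m: m.start):
            fh.write(f"{name}\t{m.start - 1}\t{m.end}\t"
                     f"G4_x{m.tract_len}\t{m.score:.2f}\t+\n")
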