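"""Barcode demultiplexing with chimera detection and read filtering.

Barcoded amplicon molecules carry their barcode at the read termini; a
qualifying barcode hit in the *interior* of a read is the signature of a
chimeric molecule (two amplicons fused during PCR or library preparation),
which would otherwise cause cross-sample assignment errors.  Reads without
any qualifying barcode hit are unclassified.  Classified reads are then
filtered on length and mean quality before alignment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import edlib
import numpy as np

from .synthgen import SimRead, reverse_complement

__all__ = ["FilterParams", "ReadClassification", "mean_qscore",
           "classify_barcode", "filter_read", "demux_reads",
           "trim_barcodes"]


@dataclass
class FilterParams:
    """Read-level filter and barcode-matching parameters."""

    min_len: int = 2_000
    max_len: int = 16_000
    min_q: float = 8.0
    max_mismatches: int = 3
    end_window: int = 150

    def __post_init__(self) -> None:
        if self.min_len >= self.max_len:
            raise ValueError("min_len must be < max_len")
        if self.min_q < 0:
            raise ValueError("min_q must be >= 0")


@dataclass
class ReadClassification:
    read_id: str
    status: str  # assigned | unclassified | chimeric | filtered
    sample_id: str | None = None
    filter_reason: str = "none"  # length_short | length_long | low_quality | none
    mean_q: float = float("nan")

    def __post_init__(self) -> None:
        if self.status not in ("assigned", "unclassified", "chimeric", "filtered"):
            raise ValueError(f"unknown status {self.status!r}")
        if (self.sample_id is not None) != (self.status == "assigned"):
            raise ValueError("sample_id present iff status is 'assigned'")


def mean_qscore(qualities: Sequence[int] | np.ndarray) -> float:
    """Mean Phred quality of a read: error probabilities are averaged first,
    then transformed, matching how sequencing QC tools summarise reads."""
    q = np.asarray(qualities, dtype=float)
    if q.size == 0:
        raise ValueError("empty quality vector")
    return float(-10.0 * np.log10(np.mean(10.0 ** (-q / 10.0))))


def _best_hit(query: str, target: str, k: int) -> int | None:
    """Best edit distance of query within target, or None if worse than k."""
    if len(target) < 1:
        return None
    r = edlib.align(query, target, mode="HW", task="distance", k=k)
    d = r["editDistance"]
    return None if d == -1 else d


def classify_barcode(read: "SimRead | tuple[str, str]",
                     barcode_set: Sequence[str],
                     params: FilterParams | None = None) -> ReadClassification:
    """Locate barcodes in a read and classify it.

    A barcode qualifies when it matches (either orientation) with at most
    ``params.max_mismatches`` errors.  A qualifying hit inside one of the two
    end windows assigns the read to that sample; a qualifying hit only (or
    additionally, from a different sample) in the interior marks the read
    chimeric, as does a conflict between the two end windows.  No qualifying
    hit anywhere leaves the read unclassified.
    """
    params = params or FilterParams()
    if not barcode_set:
        raise ValueError("empty barcode set")
    bc_len = len(barcode_set[0])
    if any(len(b) != bc_len for b in barcode_set):
        raise ValueError("barcodes must share one length")
    if params.end_window < bc_len:
        raise ValueError("end window shorter than barcode length")

    if isinstance(read, SimRead):
        rid, seq = read.read_id, read.sequence
    else:
        rid, seq = read
    w = params.end_window
    head, tail = seq[:w], seq[-w:]
    # interior with half-barcode overlap so hits straddling the window
    # boundary are not double-counted as internal
    interior = seq[w - bc_len // 2: len(seq) - w + bc_len // 2] \
        if len(seq) > 2 * w else ""

    k = params.max_mismatches
    best: dict[str, tuple[int, int]] = {}  # region -> (distance, sample idx)
    internal_hits: set[int] = set()
    for si, bc in enumerate(barcode_set):
        for query in (bc, reverse_complement(bc)):
            for region, target in (("head", head), ("tail", tail)):
                d = _best_hit(query, target, k)
                if d is not None and (region not in best or
                                      (d, si) < best[region]):
                    best[region] = (d, si)
            if interior:
                d = _best_hit(query, interior, k)
                if d is not None:
                    internal_hits.add(si)

    if internal_hits:
        return ReadClassification(rid, "chimeric")
    if "head" in best and "tail" in best and best["head"][1] != best["tail"][1]:
        return ReadClassification(rid, "chimeric")
    if not best:
        return ReadClassification(rid, "unclassified")
    _, si = min(best.values())
    return ReadClassification(rid, "assigned", sample_id=str(si))


def trim_barcodes(read: SimRead, barcode: str,
                  params: FilterParams | None = None) -> SimRead:
    """Cut the assigned barcode (and everything outside it) off both ends.

    Downstream alignment assumes reads are pure amplicon sequence; leaving
    the barcode on frame-shifts the terminal alignment columns and poisons
    breakpoint placement near the read ends.  Ends without a qualifying
    barcode hit are left untouched.
    """
    params = params or FilterParams()
    w, k = params.end_window, params.max_mismatches
    seq, quals = read.sequence, read.qualities
    start, end = 0, len(seq)
    best_head = None
    for q in (barcode, reverse_complement(barcode)):
        r = edlib.align(q, seq[:w], mode="HW", task="locations", k=k)
        if r["editDistance"] != -1 and (best_head is None
                                        or r["editDistance"] < best_head[0]):
            best_head = (r["editDistance"], r["locations"][0][1] + 1)
    if best_head is not None:
        start = best_head[1]
    best_tail = None
    tail0 = max(len(seq) - w, start)
    for q in (barcode, reverse_complement(barcode)):
        r = edlib.align(q, seq[tail0:], mode="HW", task="locations", k=k)
        if r["editDistance"] != -1 and (best_tail is None
                                        or r["editDistance"] < best_tail[0]):
            best_tail = (r["editDistance"], tail0 + r["locations"][0][0])
    if best_tail is not None:
        end = best_tail[1]
    return SimRead(read.read_id, seq[start:end], quals[start:end],
                   read.cultivar, read.homoeolog, read.copy_index,
                   read.chimera, read.barcode_present, read.template_len)


def filter_read(read: "SimRead | tuple[str, str, np.ndarray]",
                params: FilterParams | None = None) -> tuple[bool, str]:
    """Length/quality filter; returns (passed, first violated reason)."""
    params = params or FilterParams()
    if isinstance(read, SimRead):
        n, quals = len(read.sequence), read.qualities
    else:
        _, seq, quals = read
        n = len(seq)
    if n < params.min_len:
        return False, "length_short"
    if n > params.max_len:
        return False, "length_long"
    if mean_qscore(quals) < params.min_q - 1e-9:  # boundary inclusive
        return False, "low_quality"
    return True, "none"


def demux_reads(reads: Sequence[SimRead], barcode_set: Sequence[str],
                sample_ids: Sequence[str] | None = None,
                params: FilterParams | None = None) -> list[ReadClassification]:
    """Classify then filter a batch of reads.

    Every read receives exactly one terminal status: chimeric and
    unclassified take precedence (those reads are discarded before
    filtering, mirroring the order of the sequencing workflow), then the
    length/quality filter turns failing assigned reads into ``filtered``.
    """
    params = params or FilterParams()
    out = []
    for r in reads:
        c = classify_barcode(r, barcode_set, params)
        if c.status == "assigned":
            ok, reason = filter_read(r, params)
            c.mean_q = mean_qscore(r.qualities)
            if not ok:
                c = ReadClassification(r.read_id, "filtered",
                                       filter_reason=reason, mean_q=c.mean_q)
            elif sample_ids is not None:
                c.sample_id = sample_ids[int(c.sample_id)]
        out.append(c)
    return out
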