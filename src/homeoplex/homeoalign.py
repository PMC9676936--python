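"""Homoeolog assignment, coverage statistics and reference-guided consensus.

Reads from a multiplexed amplicon of homoeologous genes (~92% identical)
must be attributed to the right subgenome copy before any variant calling.
Each read is aligned to every homoeolog reference and assigned to the best
one only when the alignment passes identity/aligned-fraction floors and
beats the runner-up by a clear margin — the analog of a mapping-quality
cutoff.

Alignment is a two-pass scheme.  Pass one is a global edit-distance
alignment (read and reference end to end); terminal reference gaps are then
stripped so partial-amplicon reads behave semi-globally, and terminal read
gaps become soft clips.  Pass two repairs the gap structure: unit-cost
optimal paths are massively degenerate around large insertions and
deletions (the optimum shatters a multi-kilobase event into dozens of
fragments interleaved with spurious matches), so every dirty region between
long exact-match anchors whose net length change is large is re-fit with a
single-gap model — one explicit insertion or deletion at the
minimum-mismatch breakpoint, flanks re-aligned properly.  This keeps
multi-kilobase events as single CIGAR operations, which structural-variant
calling downstream relies on.  Identity is gap-compressed (a gap run counts
one column), the convention of long-read mappers, so an SV-carrying read is
not punished per deleted base.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import edlib
import numpy as np

from .synthgen import HomoeologReference, SimRead, reverse_complement

__all__ = ["AlignParams", "AlignedRead", "CoverageReport",
           "align_to_references", "assign_homoeolog", "align_and_assign",
           "coverage_stats", "reference_guided_consensus", "LowCoverageError",
           "write_sam"]

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


class LowCoverageError(RuntimeError):
    """Raised when too few reads exist to build a consensus."""


@dataclass
class AlignParams:
    min_identity: float = 0.80
    min_aligned_fraction: float = 0.50
    uniqueness_margin: int = 50  # edit-distance units; the mapq-analog
    min_read_len: int = 50
    anchor_min: int = 30  # exact-match run length bounding dirty regions
    consolidate_min: int = 20  # net length change that triggers a gap re-fit


@dataclass
class AlignedRead:
    """A read placed on one homoeolog reference.

    ``cigar`` is a run-length list of (op, length) with ops ``=/X/I/D/S``
    (match, mismatch, insertion-to-reference, deletion-from-reference,
    soft clip) over the read in reference orientation.  ``identity`` is
    gap-compressed (matches over match+mismatch+gap-run columns);
    ``aligned_fraction`` is the fraction of read bases placed on reference
    columns (not inserted, not clipped).
    """

    read_id: str
    ref_id: str
    ref_start: int  # 0-based half-open internally
    ref_end: int
    strand: str
    cigar: list[tuple[str, int]]
    identity: float
    aligned_fraction: float
    edit_distance: int
    sequence: str  # read sequence in reference orientation
    sample_id: str | None = None
    assignment: str = "candidate"  # unique | ambiguous | unaligned

    def __post_init__(self) -> None:
        if not (0.0 <= self.identity <= 1.0
                and 0.0 <= self.aligned_fraction <= 1.0):
            raise ValueError("identity/aligned_fraction out of [0,1]")
        read_span = sum(n for op, n in self.cigar if op in "=XIMS")
        ref_span = sum(n for op, n in self.cigar if op in "=XDM")
        if read_span != len(self.sequence) or \
                ref_span != self.ref_end - self.ref_start:
            raise ValueError("CIGAR inconsistent with read/reference spans")


def _parse_cigar(cigar: str) -> list[tuple[str, int]]:
    return [(op, int(n)) for n, op in _CIGAR_RE.findall(cigar)]


def _strip_terminal(cigar: list[tuple[str, int]]) -> tuple[
        list[tuple[str, int]], int, int]:
    """Turn terminal reference gaps into offsets and read gaps into clips.

    Returns (cigar, leading ref offset, trailing ref trim).
    """
    lead_ref = tail_ref = 0
    lead_clip = tail_clip = 0
    i, j = 0, len(cigar)
    while i < j and cigar[i][0] in "IDS":
        op, n = cigar[i]
        if op == "D":
            lead_ref += n
        else:
            lead_clip += n
        i += 1
    while j > i and cigar[j - 1][0] in "IDS":
        op, n = cigar[j - 1]
        if op == "D":
            tail_ref += n
        else:
            tail_clip += n
        j -= 1
    out = cigar[i:j]
    if lead_clip:
        out = [("S", lead_clip)] + out
    if tail_clip:
        out = out + [("S", tail_clip)]
    return out, lead_ref, tail_ref


def _trim_to_anchor(cigar: list[tuple[str, int]], anchor_min: int,
                    ) -> tuple[list[tuple[str, int]], int, int]:
    """Clip alignment ends back to the outermost exact-match anchors.

    A partial-length read forced through a global alignment can end on a
    few coincidentally matching bases beyond a huge gap, which turns the
    read's missing span into a bogus interior deletion; clipping everything
    outside the outermost >= ``anchor_min`` match runs removes it.  Returns
    (cigar, extra leading ref offset, extra trailing ref trim).
    """
    def is_anchor(op_n):
        return op_n[0] == "=" and op_n[1] >= anchor_min

    def has_big_gap(ops):
        return any(op in "ID" and n >= 20 for op, n in ops)

    first = next((i for i, c in enumerate(cigar) if is_anchor(c)), None)
    if first is None:
        qlen = sum(n for op, n in cigar if op in "=XIMS")
        return ([("S", qlen)] if qlen else []), \
            sum(n for op, n in cigar if op in "=XDM"), 0
    last = max(i for i, c in enumerate(cigar) if is_anchor(c))
    out = list(cigar)
    lead_r = tail_r = 0
    if has_big_gap(out[:first]):  # honest noisy ends stay; bogus gaps go
        lead_q = sum(n for op, n in out[:first] if op in "=XIMS")
        lead_r = sum(n for op, n in out[:first] if op in "=XDM")
        out = ([("S", lead_q)] if lead_q else []) + out[first:]
        last += 1 - first if lead_q else -first
    if has_big_gap(out[last + 1:]):
        tail_q = sum(n for op, n in out[last + 1:] if op in "=XIMS")
        tail_r = sum(n for op, n in out[last + 1:] if op in "=XDM")
        out = out[:last + 1] + ([("S", tail_q)] if tail_q else [])
    return out, lead_r, tail_r


def _hamming_prefix(q: np.ndarray, r: np.ndarray) -> np.ndarray:
    """cum[j] = mismatches between q[:j] and r[:j] (lengths may differ)."""
    m = min(q.size, r.size)
    cum = np.zeros(m + 1, dtype=np.int64)
    if m:
        cum[1:] = np.cumsum(q[:m] != r[:m])
    return cum


def _chain_anchors(q: str, r: str, k: int = 16, min_anchor: int = 20,
                   ) -> list[tuple[int, int, int]]:
    """Colinear chain of exact unique-k-mer anchors: [(q_start, r_start,
    length)].  The coarse pass of the two-pass scheme: it re-discovers the
    alignment skeleton inside a region the optimal-path degeneracy smeared.
    """
    if len(q) < k or len(r) < k:
        return []

    def unique_index(s: str) -> dict[str, int]:
        idx: dict[str, int] = {}
        dup: set[str] = set()
        for i in range(len(s) - k + 1):
            km = s[i:i + k]
            if km in idx:
                dup.add(km)
            else:
                idx[km] = i
        for km in dup:
            del idx[km]
        return idx

    qi, ri = unique_index(q), unique_index(r)
    pairs = sorted((qi[km], ri[km]) for km in qi.keys() & ri.keys())
    if not pairs:
        return []
    # longest strictly-increasing subsequence on r positions
    import bisect
    tails: list[int] = []
    links: list[int] = []
    tail_idx: list[int] = []
    for n, (_, rp) in enumerate(pairs):
        j = bisect.bisect_left(tails, rp)
        if j == len(tails):
            tails.append(rp)
            tail_idx.append(n)
        else:
            tails[j] = rp
            tail_idx[j] = n
        links.append(tail_idx[j - 1] if j else -1)
    chain = []
    n = tail_idx[len(tails) - 1]
    while n != -1:
        chain.append(pairs[n])
        n = links[n]
    chain.reverse()
    # compress same-diagonal runs into exact anchors
    anchors: list[tuple[int, int, int]] = []
    for qp, rp in chain:
        if anchors:
            qs, rs, ln = anchors[-1]
            if qp - qs == rp - rs and 0 < qp - (qs + ln - k) <= k:
                anchors[-1] = (qs, rs, qp + k - qs)
                continue
            if qp < qs + ln or rp < rs + ln:
                continue  # overlapping off-diagonal seed: drop
        anchors.append((qp, rp, k))
    return [a for a in anchors if a[2] >= min_anchor]


def _refit_region(q: str, r: str,
                  single_gap_min: int = 20) -> list[tuple[str, int]]:
    """Re-align a dirty region: coarse anchor chaining, then a single-gap
    fit between anchors.

    Within each anchor-free stretch the net length difference becomes one
    explicit insertion or deletion at the breakpoint minimising flank
    mismatches (leftmost on ties, which left-aligns events in repeats);
    flanks are re-aligned edit-distance-optimally.  Anchoring first keeps
    nearby events separate — e.g. two deletions straddling a short intact
    island stay two operations.
    """
    if min(len(q), len(r)) >= 64:
        anchors = _chain_anchors(q, r)
        if anchors:
            ops: list[tuple[str, int]] = []
            q0 = r0 = 0
            for qs, rs, ln in anchors:
                ops += _single_gap(q[q0:qs], r[r0:rs], single_gap_min)
                ops.append(("=", ln))
                q0, r0 = qs + ln, rs + ln
            ops += _single_gap(q[q0:], r[r0:], single_gap_min)
            return _merge_ops(ops)
    return _single_gap(q, r, single_gap_min)


def _single_gap(q: str, r: str,
                single_gap_min: int = 20) -> list[tuple[str, int]]:
    L = len(q) - len(r)
    # the one-gap model only beats an optimal path where the net length
    # change is too large to be scattered sequencing noise
    if abs(L) < single_gap_min:
        return _sub_path(q, r)
    qa = np.frombuffer(q.encode(), dtype=np.uint8)
    ra = np.frombuffer(r.encode(), dtype=np.uint8)
    if L > 0:
        pre = _hamming_prefix(qa, ra)
        suf_mis = qa[L:] != ra[:len(ra)] if len(ra) else np.zeros(0, bool)
        suf = np.zeros(len(ra) + 1, dtype=np.int64)
        suf[:-1] = np.cumsum(suf_mis[::-1])[::-1]
        cost = pre[:len(ra) + 1] + suf
        j = int(np.argmin(cost))
        left = _sub_path(q[:j], r[:j])
        mid = [("I", L)]
        right = _sub_path(q[j + L:], r[j:])
    else:
        D = -L
        pre = _hamming_prefix(qa, ra)
        suf_mis = qa[:len(qa)] != ra[D:] if len(qa) else np.zeros(0, bool)
        suf = np.zeros(len(qa) + 1, dtype=np.int64)
        suf[:-1] = np.cumsum(suf_mis[::-1])[::-1]
        cost = pre[:len(qa) + 1] + suf
        j = int(np.argmin(cost))
        left = _sub_path(q[:j], r[:j])
        mid = [("D", D)]
        right = _sub_path(q[j:], r[j + D:])
    return _merge_ops(left + mid + right)


def _sub_path(q: str, r: str) -> list[tuple[str, int]]:
    if not q and not r:
        return []
    if not q:
        return [("D", len(r))]
    if not r:
        return [("I", len(q))]
    res = edlib.align(q, r, mode="NW", task="path")
    return _parse_cigar(res["cigar"])


def _merge_ops(ops: list[tuple[str, int]]) -> list[tuple[str, int]]:
    out: list[tuple[str, int]] = []
    for op, n in ops:
        if n == 0:
            continue
        if out and out[-1][0] == op:
            out[-1] = (op, out[-1][1] + n)
        else:
            out.append((op, n))
    return out


def _consolidate(cigar: list[tuple[str, int]], seq: str, ref_seq: str,
                 ref_start: int, params: AlignParams) -> list[tuple[str, int]]:
    """Re-fit every dirty inter-anchor region with a large net length change.

    Anchors are exact-match runs of at least ``anchor_min``; a region whose
    insertions minus deletions exceed ``consolidate_min`` in magnitude and
    whose gap structure is fragmented gets the single-gap treatment of
    :func:`_refit_region`.
    """
    out: list[tuple[str, int]] = []
    region: list[tuple[str, int]] = []
    rp, qp = ref_start, 0
    region_r0 = rp
    region_q0 = qp

    def flush() -> None:
        nonlocal region
        if region:
            net = sum(n for op, n in region if op == "I") - \
                sum(n for op, n in region if op == "D")
            gap_runs = sum(1 for op, _ in region if op in "ID")
            if abs(net) >= params.consolidate_min and gap_runs > 1:
                out.extend(_refit_region(seq[region_q0:qp],
                                         ref_seq[region_r0:rp],
                                         params.consolidate_min))
            else:
                out.extend(region)
            region = []

    for op, n in cigar:
        if op == "S" or (op == "=" and n >= params.anchor_min):
            flush()
            out.append((op, n))
        else:
            if not region:
                region_r0, region_q0 = rp, qp
            region.append((op, n))
        if op in "=XM":
            rp += n
            qp += n
        elif op == "D":
            rp += n
        else:  # I, S
            qp += n
    flush()
    return _merge_ops(out)


def _stats(cigar: list[tuple[str, int]], read_len: int) -> tuple[
        float, float, int]:
    """(gap-compressed identity, aligned fraction, edit distance)."""
    matches = sum(n for op, n in cigar if op == "=")
    mism = sum(n for op, n in cigar if op == "X")
    gap_runs = sum(1 for op, _ in cigar if op in "ID")
    gap_bases = sum(n for op, n in cigar if op in "ID")
    cols = matches + mism + gap_runs
    identity = matches / cols if cols else 0.0
    aligned = matches + mism
    return identity, aligned / read_len, mism + gap_bases


def _stitch_path(q: str, ref_seq: str, params: AlignParams,
                 ) -> "tuple[list[tuple[str, int]], int, int] | None":
    """Seed-chain-and-stitch alignment of one oriented read.

    The coarse pass chains unique exact k-mer anchors read-vs-reference;
    the fine pass re-aligns the span between the outermost anchors with
    the gap-aware region refit and the read's overhanging ends against
    matching-length reference windows.  Returns (cigar, ref_start,
    ref_end) or None when no anchor exists (foreign or duplicated
    sequence, e.g. a same-target chimera whose k-mers are all ambiguous).
    """
    anchors = _chain_anchors(q, ref_seq, min_anchor=params.anchor_min)
    if not anchors:
        return None
    q1, r1, _ = anchors[0]
    qL, rL, lnL = anchors[-1]
    q_end, r_end = qL + lnL, rL + lnL
    ops: list[tuple[str, int]] = []
    ref_start = r1
    if q1 > 0:
        w = min(r1, q1 + 64)
        ops += _sub_path(q[:q1], ref_seq[r1 - w:r1])
        ref_start = r1 - w
    ops += _refit_region(q[q1:q_end], ref_seq[r1:r_end])
    ref_stop = r_end
    if q_end < len(q):
        w = min(len(ref_seq) - r_end, (len(q) - q_end) + 64)
        ops += _sub_path(q[q_end:], ref_seq[r_end:r_end + w])
        ref_stop = r_end + w
    return _merge_ops(ops), ref_start, ref_stop


def align_to_references(read: "SimRead | tuple[str, str]",
                        refs: Mapping[str, HomoeologReference | str],
                        params: AlignParams | None = None,
                        ) -> dict[str, AlignedRead]:
    """Two-pass candidate alignment of one read against every reference.

    Strand and reference ranking use the plain global edit distance; the
    reported path comes from the seed-chain-and-stitch scheme, with
    terminal reference gaps stripped (semi-global behaviour) and bogus
    gap-bearing terminal segments clipped.
    """
    params = params or AlignParams()
    if isinstance(read, SimRead):
        rid, seq = read.read_id, read.sequence
    else:
        rid, seq = read
    if len(seq) < params.min_read_len:
        raise ValueError(f"read {rid} shorter than {params.min_read_len} bases")
    rc_seq = reverse_complement(seq)
    out: dict[str, AlignedRead] = {}
    for ref_id, ref in refs.items():
        ref_seq = ref.sequence if isinstance(ref, HomoeologReference) else ref
        fw = edlib.align(seq, ref_seq, mode="NW", task="distance")
        rc = edlib.align(rc_seq, ref_seq, mode="NW", task="distance")
        strand = "-" if rc["editDistance"] < fw["editDistance"] else "+"
        oriented = rc_seq if strand == "-" else seq
        stitched = _stitch_path(oriented, ref_seq, params)
        if stitched is None:
            out[ref_id] = AlignedRead(
                read_id=rid, ref_id=ref_id, ref_start=0, ref_end=0,
                strand=strand, cigar=[("S", len(oriented))], identity=0.0,
                aligned_fraction=0.0, edit_distance=len(oriented),
                sequence=oriented)
            continue
        cigar, ref_start, ref_stop = stitched
        cigar, lead_ref, tail_ref = _strip_terminal(cigar)
        ref_start += lead_ref
        cigar, lead2, tail2 = _trim_to_anchor(cigar, params.anchor_min)
        ref_start += lead2
        cigar, lead3, tail3 = _strip_terminal(cigar)
        ref_start += lead3
        ref_end = ref_stop - tail_ref - tail2 - tail3
        identity, af, dist = _stats(cigar, len(oriented))
        out[ref_id] = AlignedRead(
            read_id=rid, ref_id=ref_id, ref_start=ref_start, ref_end=ref_end,
            strand=strand, cigar=cigar, identity=identity,
            aligned_fraction=af, edit_distance=dist, sequence=oriented)
    return out


def assign_homoeolog(candidates: Mapping[str, AlignedRead],
                     params: AlignParams | None = None) -> AlignedRead:
    """Pick the best candidate and set its assignment status.

    ``unaligned`` when even the best alignment fails the identity or
    aligned-fraction floor; ``ambiguous`` when the runner-up is within the
    uniqueness margin (in edit-distance units); ``unique`` otherwise.  Only
    unique assignments feed variant calling.
    """
    params = params or AlignParams()
    if not candidates:
        raise ValueError("no candidates")
    ranked = sorted(candidates.values(),
                    key=lambda a: (a.edit_distance, a.ref_id))
    best = ranked[0]
    if best.identity < params.min_identity or \
            best.aligned_fraction < params.min_aligned_fraction:
        best.assignment = "unaligned"
    elif len(ranked) > 1 and \
            ranked[1].edit_distance - best.edit_distance < params.uniqueness_margin:
        best.assignment = "ambiguous"
    else:
        best.assignment = "unique"
    return best


def align_and_assign(reads: Sequence["SimRead | tuple[str, str]"],
                     refs: Mapping[str, HomoeologReference | str],
                     params: AlignParams | None = None,
                     sample_ids: Mapping[str, str] | None = None,
                     ) -> list[AlignedRead]:
    """Convenience loop: align every read, assign, attach sample ids."""
    out = []
    for r in reads:
        cands = align_to_references(r, refs, params)
        a = assign_homoeolog(cands, params)
        if sample_ids is not None:
            a.sample_id = sample_ids.get(a.read_id)
        out.append(a)
    return out


# ---------------------------------------------------------------------------
# coverage
# ---------------------------------------------------------------------------

@dataclass
class CoverageReport:
    """Per-homoeolog sequencing depth summaries across samples."""

    depth: "object"  # DataFrame samples x homoeologs, mean aligned depth
    cv: dict[str, float] = field(default_factory=dict)
    ratios: "object | None" = None  # DataFrame of pairwise depth ratios
    low_coverage: list[tuple[str, str]] = field(default_factory=list)


def coverage_stats(assignments: Sequence[AlignedRead],
                   ref_lengths: Mapping[str, int],
                   low_coverage_threshold: float = 11.0) -> CoverageReport:
    """Depth per sample and homoeolog from uniquely assigned reads.

    Depth is total aligned reference span divided by reference length.  The
    coefficient of variation (sample SD / mean across samples) summarises
    between-sample variability per homoeolog; pairwise depth ratios flag
    amplification bias between homoeologs within a sample.
    """
    import pandas as pd

    rows = [(a.sample_id or "sample", a.ref_id, a.ref_end - a.ref_start)
            for a in assignments if a.assignment == "unique"]
    if not rows:
        raise ValueError("no uniquely assigned reads")
    df = pd.DataFrame(rows, columns=["sample", "homoeolog", "span"])
    depth = (df.groupby(["sample", "homoeolog"])["span"].sum().unstack(
        fill_value=0.0))
    for h in ref_lengths:
        if h not in depth.columns:
            depth[h] = 0.0
        depth[h] = depth[h] / ref_lengths[h]
    depth = depth[sorted(ref_lengths)]
    cv = {}
    for h in depth.columns:
        m = depth[h].mean()
        cv[h] = float(depth[h].std(ddof=1) / m) if m > 0 and len(depth) > 1 \
            else float("nan")
    homs = list(depth.columns)
    ratios = pd.DataFrame(index=depth.index)
    for i, a in enumerate(homs):
        for b in homs[i + 1:]:
            denom = depth[b]
            ratios[f"{a}/{b}"] = depth[a].where(denom > 0) / denom.where(
                denom > 0)
    low = [(s, h) for s in depth.index for h in homs
           if depth.loc[s, h] < low_coverage_threshold]
    return CoverageReport(depth=depth, cv=cv, ratios=ratios, low_coverage=low)


# ---------------------------------------------------------------------------
# consensus
# ---------------------------------------------------------------------------

def reference_guided_consensus(alignments: Sequence[AlignedRead],
                               ref: HomoeologReference | str,
                               min_reads: int = 3,
                               ) -> tuple[str, np.ndarray]:
    """Column-wise majority consensus over reads aligned to one reference.

    Every reference column votes among {A, C, G, T, gap}; a gap majority
    deletes the column, so deletions carried by the reads propagate into the
    consensus.  An insertion is emitted after a column when more than half
    of the reads spanning it carry one there (the most common inserted
    sequence wins; ties break lexicographically).  Remaining ties break
    toward the reference base, which keeps the consensus conservative and
    deterministic.  Returns the consensus and per-consensus-base read depth.
    """
    from .snpcall import build_pileup

    ref_seq = ref.sequence if isinstance(ref, HomoeologReference) else ref
    usable = [a for a in alignments if a.assignment in ("unique", "candidate")]
    if len(usable) < min_reads:
        raise LowCoverageError(
            f"{len(usable)} reads < min_reads={min_reads}")
    pile = build_pileup(usable, ref_seq)
    counts = pile.counts  # (5, L): A C G T del
    depth = counts.sum(axis=0)
    ref_codes = pile.ref_codes
    best = counts.max(axis=0)
    out: list[str] = []
    depths: list[int] = []
    alpha = "ACGT-"
    for j in range(len(ref_seq)):
        if depth[j] == 0:  # uncovered: keep the reference base
            out.append(ref_seq[j])
            depths.append(0)
        else:
            winners = [i for i in range(5) if counts[i, j] == best[j]]
            if ref_codes[j] in winners:
                pick = ref_codes[j]  # tie (or win) goes to the reference
            else:
                pick = winners[0]  # fixed A<C<G<T<- order: deterministic
            if alpha[pick] != "-":
                out.append(alpha[pick])
                depths.append(int(depth[j]))
        ins = pile.insertions.get(j + 1)
        spanning = depth[min(j + 1, len(ref_seq) - 1)] if j + 1 < len(ref_seq) \
            else depth[j]
        if ins is not None and spanning > 0:
            support = sum(ins.values())
            if support * 2 > spanning:
                seq = min(s for s, c in ins.items()
                          if c == max(ins.values()))
                out.append(seq)
                depths.extend([int(support)] * len(seq))
    return "".join(out), np.asarray(depths, dtype=np.int32)


# ---------------------------------------------------------------------------
# SAM output
# ---------------------------------------------------------------------------

def write_sam(alignments: Sequence[AlignedRead],
              refs: Mapping[str, HomoeologReference | str], path) -> None:
    """Write assigned alignments as SAM (via pysam, =/X CIGAR kept)."""
    import pysam

    ref_items = [(h, r.sequence if isinstance(r, HomoeologReference) else r)
                 for h, r in sorted(refs.items())]
    header = {"HD": {"VN": "1.6", "SO": "unknown"},
              "SQ": [{"SN": h, "LN": len(s)} for h, s in ref_items]}
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for a in alignments:
            if a.assignment not in ("unique", "ambiguous"):
                continue
            seg = pysam.AlignedSegment(fh.header)
            seg.query_name = a.read_id
            seg.query_sequence = a.sequence
            seg.flag = 16 if a.strand == "-" else 0
            seg.reference_id = fh.header.references.index(a.ref_id)
            seg.reference_start = a.ref_start
            seg.mapping_quality = 60 if a.assignment == "unique" else 0
            seg.cigarstring = "".join(f"{n}{op}" for op, n in a.cigar)
            seg.set_tag("NM", a.edit_distance)
            fh.write(seg)
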