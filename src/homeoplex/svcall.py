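"""Structural-variant calling from homoeolog alignments.

Insertions and deletions of >= 30 bp are read directly off the alignment
CIGARs (the aligner is edit-distance optimal, so a multi-kilobase event
stays one operation), clustered across reads by position, and reported only
with sufficient read support.  Insertions whose sequence matches the
reference flank are reclassified as tandem duplications — the class of
event that short reads systematically miss.  Per-sample calls merge into a
population table on position proximity.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import edlib
import numpy as np

from .homeoalign import AlignedRead
from .synthgen import HomoeologReference

__all__ = ["SVParams", "SVCall", "call_svs", "classify_insertion",
           "merge_svs", "write_sv_vcf"]


@dataclass
class SVParams:
    min_len: int = 30  # events below this belong to the small-indel caller
    min_support: int = 10
    cluster_window: int = 100  # clustering reads into one event
    merge_window: int = 500  # merging calls across samples
    dup_flank_identity: float = 0.9


@dataclass
class SVCall:
    ref_id: str
    position: int  # 1-based; first deleted base / first inserted base
    type: str  # INS | DEL | DUP
    length: int
    support: int
    sample_id: str | None = None
    sequence: str = ""  # inserted sequence (INS/DUP)
    rep_position: int = 0  # anchor of the representative insert read
    members: tuple = ()  # up to five longest (anchor, insert) observations
    carriers: tuple[str, ...] = ()
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.type not in ("INS", "DEL", "DUP"):
            raise ValueError(f"unknown SV type {self.type!r}")
        if self.support < 1:
            raise ValueError("support must be >= 1")


def _events(a: AlignedRead, min_len: int, join_min: int = 10,
            join_pad: int = 100):
    """Per-read SV events: (type, 1-based position, length, sequence).

    Deletions come straight off long D operations.  Insertions additionally
    chain-join: in a tandem repeat the aligner may leave an insertion in
    several fragments separated by (real) matches inside the repeat, so
    I runs of at least ``join_min`` seed chains that absorb any further
    insertion within the chain's accumulated net length plus ``join_pad``
    of the chain start (span bounded by net: scattered point-indel noise
    cannot be swept up indefinitely).  D runs falling inside a chain's
    span count against its net instead of becoming deletion events — they
    are the same event's alignment noise.  The chain's sequence is the
    fragment concatenation (a rotation of the inserted copy).  Events
    shorter than ``min_len`` are dropped at the end.
    """
    rp, qp = a.ref_start, 0
    dels: list[tuple[int, int]] = []  # (pos, len)
    ins: list[tuple[int, int, str]] = []
    for op, n in a.cigar:
        if op in "=XM":
            rp += n
            qp += n
        elif op == "D":
            dels.append((rp + 1, n))
            rp += n
        elif op in "IS":
            if op == "I":
                ins.append((rp + 1, n, a.sequence[qp:qp + n]))
            qp += n
    # chains of insertion fragments; 1-2 bp runs are single-base stutter
    # noise, not event fragments, and must not inflate the chain
    chains: list[list[int]] = []  # index lists into `ins`
    current: list[int] = []
    for i, (pos, ln, _) in enumerate(ins):
        if ln < 3:
            continue
        if current:
            first = ins[current[0]][0]
            net = sum(ins[k][1] for k in current)
            if pos - first <= net + join_pad:
                current.append(i)
                continue
            if any(ins[k][1] >= join_min for k in current):
                chains.append(current)
            current = []
        if ln >= join_min:
            current = [i]
    if current and any(ins[k][1] >= join_min for k in current):
        chains.append(current)
    spans = []
    for chain in chains:
        first = ins[chain[0]][0]
        last = ins[chain[-1]][0]
        gross = sum(ins[k][1] for k in chain)
        eaten = sum(ln for pos, ln in dels if first <= pos <= last)
        net = gross - eaten
        seq = "".join(ins[k][2] for k in chain)
        spans.append((first, last))
        if net >= min_len:
            yield ("INS", first, net, seq)
    for pos, ln in dels:
        if ln >= min_len and not any(s <= pos <= e for s, e in spans):
            yield ("DEL", pos, ln, "")


def _polished_insert_length(seqs: Sequence[str]) -> int:
    """Length of the majority-vote consensus of the member insert
    sequences, aligned to the longest member.

    Per-read insert lengths inherit the sequencer's net indel bias
    (deletion errors outnumber insertions), so neither a single member
    nor the member median is unbiased; the column-wise majority over all
    members recovers the true length to within a base or two.
    """
    backbone = max(seqs, key=lambda s: (len(s), s))
    L = len(backbone)
    if L == 0 or len(seqs) < 3:
        return L
    import re
    votes = np.zeros((2, L), dtype=np.int32)  # base vs gap votes
    ins_events: dict[int, list[int]] = {}
    for s in seqs:
        res = edlib.align(s, backbone, mode="NW", task="path")
        rp = qp = 0
        for n_s, op in re.findall(r"(\d+)([=XIDM])", res["cigar"]):
            n = int(n_s)
            if op in "=XM":
                votes[0, rp:rp + n] += 1
                rp += n
                qp += n
            elif op == "D":
                votes[1, rp:rp + n] += 1
                rp += n
            else:
                ins_events.setdefault(rp, []).append(n)
                qp += n
    # ties break toward presence: deletion errors aggregate on single
    # columns inside homopolymer runs, so a 50:50 column is far more
    # likely a run casualty than a backbone artifact
    length = int((votes[0] >= votes[1]).sum())
    half = len(seqs) / 2
    for col, lens in ins_events.items():
        if len(lens) > half:
            length += int(np.median(lens))
    return length


def call_svs(alignments: Sequence[AlignedRead],
             params: SVParams | None = None,
             sample_id: str | None = None) -> list[SVCall]:
    """Cluster long indel operations across reads into supported SV calls.

    Events of one type cluster while consecutive positions stay within the
    cluster window; a cluster becomes a call when its read support reaches
    ``min_support``.  Position and length are cluster medians — robust to
    the indel wobble of noisy long reads.
    """
    params = params or SVParams()
    by_type: dict[tuple[str, str], list[tuple[int, int, str]]] = {}
    for a in alignments:
        if a.assignment not in ("unique", "candidate"):
            continue
        for t, pos, ln, seq in _events(a, params.min_len):
            by_type.setdefault((a.ref_id, t), []).append((pos, ln, seq))
    calls: list[SVCall] = []
    for (ref_id, t), events in by_type.items():
        events.sort()
        cluster: list[tuple[int, int, str]] = []
        for ev in events + [(10 ** 12, 0, "")]:  # sentinel flushes the last
            # insertion positions wander across a tandem repeat (any edge
            # is a valid anchor), so their clustering window widens by the
            # event length; deletions are reference-anchored and stay tight
            gap = params.cluster_window + (ev[1] if t == "INS" else 0)
            if cluster and ev[0] - cluster[-1][0] > gap:
                if len(cluster) >= params.min_support:
                    positions = [e[0] for e in cluster]
                    lengths = [e[1] for e in cluster]
                    med_len = int(np.median(lengths))
                    seq, rep_pos, members = "", 0, ()
                    if t == "INS":
                        # longest member: single-molecule deletion errors
                        # bias insert sequences short, and extra inserted
                        # bases are harmless to downstream flank matching
                        top = sorted(cluster, key=lambda e: (-e[1], e[2]))
                        seq, rep_pos = top[0][2], top[0][0]
                        members = tuple((e[0], e[2]) for e in top[:5])
                        med_len = _polished_insert_length(
                            [e[2] for e in cluster])
                    calls.append(SVCall(
                        ref_id=ref_id, position=int(np.median(positions)),
                        type=t, length=med_len, support=len(cluster),
                        sample_id=sample_id, sequence=seq,
                        rep_position=rep_pos,
                        members=members if t == "INS" else ()))
                cluster = []
            if ev[1] > 0:
                cluster.append(ev)
    calls.sort(key=lambda c: (c.ref_id, c.position))
    return calls


def _prefix_profile(query: str, target: str) -> np.ndarray:
    """profile[k] = best edit distance of query[:k] against a prefix of
    target (start pinned, target end free; numpy row recurrence)."""
    q = np.frombuffer(query.encode(), dtype=np.uint8)
    t = np.frombuffer(target.encode(), dtype=np.uint8)
    idx = np.arange(t.size + 1, dtype=np.int64)
    prev = idx.copy()  # pinned start: skipping target bases costs
    profile = np.empty(q.size + 1, dtype=np.int64)
    profile[0] = 0
    for i in range(q.size):
        cur = np.empty_like(prev)
        cur[0] = i + 1
        cur[1:] = np.minimum(prev[:-1] + (t != q[i]), prev[1:] + 1)
        cur = np.minimum.accumulate(cur - idx) + idx
        prev = cur
        profile[i + 1] = cur.min()  # free target end
    return profile


def _flank_extent(flank: str, insert: str) -> tuple[int, int]:
    """(Length, errors) of the flank prefix explained by the insert.

    Local-alignment scoring (match +1, error -3; unrelated sequence still
    aligns at ~0.45 errors per base once gaps are free, so the penalty
    must exceed ~2.2 for junk to score negative): the score climbs while
    the flank tracks the inserted copy and falls once it leaves it, so
    the argmax sits at the repeat junction — exactly for clean data,
    within a few bases under sequencing noise.
    """
    if not flank or not insert:
        return 0, 0
    prof = _prefix_profile(flank, insert)
    scores = np.arange(prof.size) - 3 * prof
    best = int(scores.argmax())
    # a handful of bases can match by chance; only substantial extents
    # are evidence of repeat content
    if best < 10 or scores[best] <= 0:
        return 0, 0
    return best, int(prof[best])


def classify_insertion(call: SVCall, ref: HomoeologReference | str,
                       params: SVParams | None = None) -> SVCall:
    """Reclassify an insertion as a tandem duplication, with a
    reference-anchored length.

    An insertion of ``r`` at position p is a tandem duplication of the
    reference unit [p−u, p+v) exactly when r's prefix copies the following
    v reference bases and r's suffix copies the preceding u bases (the
    aligner may anchor the event anywhere inside the repeat, which is
    just a different u/v split).  Both extents are measured with anchored
    local alignment; when their sum reaches ``dup_flank_identity`` of the
    insert length, the call becomes a DUP whose length is that span —
    read off the reference, so it does not inherit the net indel bias of
    read-borne insert sequences — positioned at the downstream junction.
    """
    params = params or SVParams()
    if call.type != "INS":
        return call
    if not call.sequence:
        return replace(call, flags=call.flags + ("no_sequence",))
    seq = ref.sequence if isinstance(ref, HomoeologReference) else ref
    # each observation's u/v split is tied to where the aligner anchored
    # that read's insert; aggregating several members makes the junction
    # estimate robust to error clusters in any single read
    members = call.members or ((call.rep_position or call.position,
                                call.sequence),)
    votes, spans, positions = 0, [], []
    clean_len = None
    for pos, r in members:
        p0 = pos - 1
        L = len(r)
        W = int(1.5 * L) + 20
        pre = seq[max(p0 - W, 0):p0]
        post = seq[p0:p0 + W]
        ext_pre, err_pre = _flank_extent(pre[::-1], r[::-1])
        ext_post, err_post = _flank_extent(post, r)
        span = ext_pre + ext_post
        if span >= params.dup_flank_identity * L:
            votes += 1
            spans.append(span)
            positions.append(pos + ext_post)
            if err_pre == 0 and err_post == 0 and clean_len is None:
                # a perfectly flank-matched insert is an exact unit copy
                clean_len = L
    if votes * 2 > len(members):
        length = clean_len if clean_len is not None else             int(np.median(spans))
        return replace(call, type="DUP", length=length,
                       position=int(np.median(positions)))
    return call


def merge_svs(calls: Sequence[SVCall],
              merge_window: int | None = None) -> list[SVCall]:
    """Merge per-sample calls into population records.

    Calls of the same type on the same reference chain-merge while
    consecutive positions differ by at most ``merge_window``; different
    types never merge.  Merged position/length are medians of the members;
    ``carriers`` lists the contributing samples.
    """
    window = merge_window if merge_window is not None else SVParams().merge_window
    groups: dict[tuple[str, str], list[SVCall]] = {}
    for c in calls:
        groups.setdefault((c.ref_id, c.type), []).append(c)
    merged: list[SVCall] = []
    for (ref_id, t), members in groups.items():
        members.sort(key=lambda c: c.position)
        bucket: list[SVCall] = []
        for c in members + [None]:
            if bucket and (c is None or
                           c.position - bucket[-1].position > window):
                merged.append(SVCall(
                    ref_id=ref_id,
                    position=int(np.median([b.position for b in bucket])),
                    type=t,
                    length=int(np.median([b.length for b in bucket])),
                    support=sum(b.support for b in bucket),
                    sequence=bucket[0].sequence,
                    carriers=tuple(sorted({b.sample_id or "sample"
                                           for b in bucket}))))
                bucket = []
            if c is not None:
                bucket.append(c)
    merged.sort(key=lambda c: (c.ref_id, c.position, c.type))
    return merged


def write_sv_vcf(calls: Sequence[SVCall],
                 refs: Mapping[str, HomoeologReference | str], path) -> None:
    """SV calls as VCF 4.2 with SVTYPE/SVLEN/END/SUPPORT INFO fields."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for h, r in sorted(refs.items()):
            ln = len(r.sequence if isinstance(r, HomoeologReference) else r)
            fh.write(f"##contig=<ID={h},length={ln}>\n")
        for field_ in ('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">',
                       '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">',
                       '##INFO=<ID=END,Number=1,Type=Integer,Description="End position">',
                       '##INFO=<ID=SUPPORT,Number=1,Type=Integer,Description="Supporting reads">',
                       '##INFO=<ID=CARRIERS,Number=.,Type=String,Description="Carrier samples">',
                       '##ALT=<ID=DEL,Description="Deletion">',
                       '##ALT=<ID=INS,Description="Insertion">',
                       '##ALT=<ID=DUP,Description="Tandem duplication">'):
            fh.write(field_ + "\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in sorted(calls, key=lambda c: (c.ref_id, c.position)):
            r = refs[c.ref_id]
            seq = r.sequence if isinstance(r, HomoeologReference) else r
            pos = max(c.position - 1, 1)
            ref_al = seq[pos - 1]
            end = c.position + (c.length if c.type == "DEL" else 0) - 1
            svlen = -c.length if c.type == "DEL" else c.length
            info = (f"SVTYPE={c.type};SVLEN={svlen};END={end};"
                    f"SUPPORT={c.support}")
            if c.carriers:
                info += ";CARRIERS=" + ",".join(c.carriers)
            fh.write(f"{c.ref_id}\t{pos}\t.\t{ref_al}\t<{c.type}>\t.\tPASS\t"
                     f"{info}\n")
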