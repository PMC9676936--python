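"""Shared test utilities: independent oracles and simulation shortcuts."""

from __future__ import annotations

import numpy as np

from homeoplex import catalog as cat
from homeoplex import synthgen as sg
from homeoplex.g4scan import G4Params, _score
from homeoplex.homeoalign import align_and_assign
from homeoplex.phasecn import (allele_dosage, copy_number, dosage_cluster,
                               phase_haplotypes)
from homeoplex.snpcall import build_pileup

AMPLICON_ONLY = {"barcode_loss_prob": 1.0}  # reads without barcodes


def levenshtein(a: str, b: str) -> int:
    """Quadratic-time unit-cost edit distance (numpy row recurrence).

    Independent oracle for alignment distances; the insertion dependency
    within a row is resolved with the prefix-minimum trick.
    """
    A = np.frombuffer(a.encode(), dtype=np.uint8)
    B = np.frombuffer(b.encode(), dtype=np.uint8)
    prev = np.arange(B.size + 1, dtype=np.int64)
    idx = np.arange(B.size + 1, dtype=np.int64)
    for i in range(A.size):
        cur = np.empty_like(prev)
        cur[0] = i + 1
        cur[1:] = np.minimum(prev[:-1] + (B != A[i]), prev[1:] + 1)
        cur = np.minimum.accumulate(cur - idx) + idx
        prev = cur
    return int(prev[-1])


def brute_force_g4(seq: str, p: G4Params):
    """Exhaustive G4 decomposition enumeration + greedy selection.

    Independent of the scanner: direct string-slice tract checks over all
    (start, tract length, loop triple) combinations.
    """
    cands = []
    n = len(seq)
    maxloop = p.max_loop if p.max_loop is not None else p.max_len - 4 * p.min_tract
    for s in range(n):
        for x in range(p.min_tract, p.max_len // 4 + 1):
            if seq[s:s + x] != "G" * x:
                break
            budget = p.max_len - 4 * x
            for y1 in range(0, min(maxloop, budget) + 1):
                t2 = s + x + y1
                if seq[t2:t2 + x] != "G" * x:
                    continue
                for y2 in range(0, min(maxloop, budget - y1) + 1):
                    t3 = t2 + x + y2
                    if seq[t3:t3 + x] != "G" * x:
                        continue
                    for y3 in range(0, min(maxloop, budget - y1 - y2) + 1):
                        t4 = t3 + x + y3
                        if t4 + x > n or seq[t4:t4 + x] != "G" * x:
                            continue
                        loops = (y1, y2, y3)
                        cands.append((s, t4 + x, x, loops,
                                      _score(x, loops, p)))
    cands.sort(key=lambda c: (-c[4], c[0], -c[2], c[1]))
    chosen, taken = [], []
    for s, e, x, loops, sc in cands:
        if any(s < te and ts < e for ts, te in taken):
            continue
        taken.append((s, e))
        chosen.append((s + 1, e, x, loops, sc))
    return chosen


def planted_a1_sites() -> dict[int, set[str]]:
    """Catalog site -> set of non-reference alleles planted panel-wide."""
    ref_row = cat.VRN_A1_GROUP_ALLELES["GT3"]
    out: dict[int, set[str]] = {}
    for row in cat.VRN_A1_GROUP_ALLELES.values():
        for i, (a, r) in enumerate(zip(row, ref_row)):
            if a != r:
                out.setdefault(cat.VRN_A1_POSITIONS[i], set()).add(a)
    return out


def simulate_sv_alignments(refs, alleles, n_reads, seed,
                           error_model=None, hom=None):
    """Simulate reads for one SV-carrying cultivar and align to all refs."""
    em = error_model or sg.ErrorModel.error_free(**AMPLICON_ONLY)
    gt = cat.sv_genotype("cv", alleles)
    hom = hom or cat.SV_ALLELES[alleles[0]][0]
    reads, _ = sg.simulate_panel([gt], refs, n_reads, em,
                                 sg.make_barcodes(4), seed,
                                 full_length_prob=1.0)
    sub = [r for r in reads if r.homoeolog == hom]
    return [a for a in align_and_assign(sub, refs)
            if a.assignment == "unique" and a.ref_id == hom]


# ---------------------------------------------------------------------------
# copy-number grid on a phasing window
# ---------------------------------------------------------------------------
# To keep the simulation grid desk-scale, phasing/dosage recovery runs on a
# 1.3 kb sub-amplicon containing two het-capable catalog sites ~600 bp
# apart, rather than the full 13.7 kb gene; the classifier logic is
# identical.
CN_WINDOW = (3900, 5200)
CN_SITES = (4138, 4757)  # intron-1 G/A het sites


def cn_config(cn: int):
    w0 = CN_WINDOW[0]
    s1, s2 = CN_SITES[0] - w0, CN_SITES[1] - w0
    a1 = sg.AlleleEdit("SNP", s1, 1, "A")
    a2 = sg.AlleleEdit("SNP", s2, 1, "A")
    haps = {
        1: [()],
        2: [(), (a2,)],
        3: [(a2,), (a2,), ()],
        4: [(), (a2,), (a1,), (a1, a2)],
    }[cn]
    return [sg.TemplateCopy(edits=e, haplotype=f"h{i}", weight=1 / len(haps))
            for i, e in enumerate(haps)]


def run_cn_trial(refs, cn: int, seed: int, depth: int = 300) -> int:
    """Simulate one copy-number configuration and classify it."""
    w0, w1 = CN_WINDOW
    window = refs["A"].sequence[w0:w1]
    s1, s2 = CN_SITES[0] - w0, CN_SITES[1] - w0
    gt = sg.CultivarGenotype("cv", {"A": cn_config(cn)})
    em = sg.ErrorModel(**AMPLICON_ONLY)
    reads, _ = sg.simulate_panel([gt], {"A": window}, depth, em,
                                 sg.make_barcodes(4), seed,
                                 full_length_prob=0.9)
    alns = align_and_assign(reads, {"A": window})
    pile = build_pileup(alns, window, ref_id="A")
    hs = phase_haplotypes(alns, [s1, s2], 10,
                          {s1: {"G", "A"}, s2: {"G", "A"}},
                          realign_ref=window)
    dos = allele_dosage(pile, s2, "A", alignments=alns)
    zyg = "het" if cn > 1 else "hom"
    return copy_number(hs, dosage_cluster(dos), zyg).copy_number
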