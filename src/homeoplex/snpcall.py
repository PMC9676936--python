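"""Pileup-based SNP and small-indel calling with noise-aware filters.

Long-read amplicon data has ample depth but a high raw error rate, so the
caller leans on three filters: a minor-allele count floor (>= 3), a
Phred-scaled site quality derived from the binomial tail of the allele
count against the background error rate (>= 30), and exclusion of calls in
homopolymeric context, where single-molecule sequencers concentrate their
indel errors.  Heterozygous calls additionally require the minor allele to
reach a frequency floor, tolerant of dosage imbalance up to 4:1 so that
multi-copy genes with unequal allele dosage (e.g. 2:1) still call het.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import edlib
import numpy as np
from scipy import stats

from .homeoalign import AlignedRead
from .synthgen import HomoeologReference, _homopolymer_mask, _to_codes

__all__ = ["Pileup", "SmallVariantCall", "SnpParams", "build_pileup",
           "call_variants", "homopolymer_filter", "indel_shadow_filter",
           "consensus_indels", "realign_allele", "realigned_site_counts",
           "realigned_counts_multi", "variant_positions", "write_vcf"]


@dataclass
class SnpParams:
    min_depth: int = 11
    min_count: int = 3
    min_freq: float = 0.20
    min_qual: float = 30.0
    error_rate: float = 0.05  # per-allele background used for site quality
    homopolymer_run: int = 4
    # Indel alleles default to the consensus route (consensus_indels):
    # alignment normalisation concentrates single-molecule indel errors from
    # a whole repeat neighbourhood onto one pileup column, where they can
    # reach tens of percent — column-frequency rules are only trustworthy
    # for substitutions.  Set True to call indel alleles from the pileup too.
    call_indels: bool = False


@dataclass
class Pileup:
    """Per-position allele tallies over one reference.

    ``counts`` is a (5, L) array over {A, C, G, T, deletion}; insertions are
    kept separately as Counters of inserted sequence keyed by the 0-based
    reference column *before which* the insertion occurs.
    """

    ref_id: str
    ref_seq: str
    counts: np.ndarray
    insertions: dict[int, dict[str, int]] = field(default_factory=dict)

    @property
    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def ref_codes(self) -> np.ndarray:
        return _to_codes(self.ref_seq)


@dataclass
class SmallVariantCall:
    ref_id: str
    position: int  # 1-based amplicon coordinate
    ref_allele: str  # base, or "-" for an insertion site
    alleles: tuple[str, ...]  # called alleles; "-" = deletion allele
    counts: dict[str, int]
    zygosity: str  # hom | het
    quality: float
    kind: str  # SNP | DEL | INS
    filter: str = "pass"  # pass | homopolymer

    def __post_init__(self) -> None:
        if self.zygosity == "het" and len(self.alleles) != 2:
            raise ValueError("het call must carry exactly two alleles")


def build_pileup(alignments: Sequence[AlignedRead],
                 ref: HomoeologReference | str,
                 ref_id: str = "ref") -> Pileup:
    """Tally every aligned base and gap at its reference position.

    Consumes reads in reference orientation (as produced by the aligner);
    insertion operations are recorded at the column they precede.
    """
    ref_seq = ref.sequence if isinstance(ref, HomoeologReference) else ref
    L = len(ref_seq)
    counts = np.zeros((5, L), dtype=np.int32)
    insertions: dict[int, dict[str, int]] = {}
    for a in alignments:
        codes = _to_codes(a.sequence)
        rp, qp = a.ref_start, 0
        for op, n in a.cigar:
            if op in "=XM":
                np.add.at(counts, (codes[qp:qp + n], np.arange(rp, rp + n)),
                          1)
                rp += n
                qp += n
            elif op == "D":
                counts[4, rp:rp + n] += 1
                rp += n
            elif op == "I":
                seq = a.sequence[qp:qp + n]
                insertions.setdefault(rp, {})
                insertions[rp][seq] = insertions[rp].get(seq, 0) + 1
                qp += n
            else:  # soft clips and exotica are ignored
                qp += n
    return Pileup(ref_id=ref_id, ref_seq=ref_seq, counts=counts,
                  insertions=insertions)


def _query_span(a: AlignedRead, r0: int, r1: int) -> tuple[int, int] | None:
    """Query index interval aligned to the 0-based ref window [r0, r1)."""
    rp, qp = a.ref_start, 0
    q0 = q1 = None
    if not (a.ref_start <= r0 and r1 <= a.ref_end):
        return None
    for op, n in a.cigar:
        if op in "=XM":
            if q0 is None and rp + n > r0:
                q0 = qp + max(r0 - rp, 0)
            if rp + n >= r1:
                q1 = qp + (r1 - rp)
                return (q0, q1) if q0 is not None else None
            rp += n
            qp += n
        elif op == "D":
            if q0 is None and rp + n > r0:
                q0 = qp
            if rp + n >= r1:
                return (q0, qp) if q0 is not None else None
            rp += n
        else:  # I, S
            qp += n
    return None


def realign_allele(a: AlignedRead, ref_seq: str, position: int,
                   alleles: Sequence[str], window: int = 20) -> str | None:
    """Allele call for one read at one site by local realignment.

    Unit-cost alignment paths are reference-biased at substitution sites
    flanked by indel noise (the optimal path can route the alternate base
    into a gap and show the reference base instead), so per-read allele
    extraction re-aligns the read segment spanning the site against one
    candidate haplotype window per allele and picks the closest;
    ties return None (ambiguous).  The deletion allele is written ``-``.
    """
    j = position - 1
    r0, r1 = max(j - window, 0), min(j + 1 + window, len(ref_seq))
    span = _query_span(a, r0, r1)
    if span is None:
        return None
    seg = a.sequence[span[0]:span[1]]
    if not seg:
        return None
    best: list[tuple[int, str]] = []
    for al in alleles:
        if al == "-":
            variant = ref_seq[r0:j] + ref_seq[j + 1:r1]
        elif al.startswith("+"):
            variant = ref_seq[r0:j + 1] + al[1:] + ref_seq[j + 1:r1]
        else:
            variant = ref_seq[r0:j] + al + ref_seq[j + 1:r1]
        d = edlib.align(seg, variant, mode="NW",
                        task="distance")["editDistance"]
        best.append((d, al))
    best.sort()
    if len(best) > 1 and best[0][0] == best[1][0]:
        return None
    return best[0][1]


def _ref_to_query_map(a: AlignedRead) -> np.ndarray:
    """query index at the start of each reference offset of the alignment
    (length ref span + 1; the sentinel is the query index past the end)."""
    span = a.ref_end - a.ref_start
    m = np.empty(span + 1, dtype=np.int64)
    rp, qp = 0, 0
    sentinel = None
    for op, n in a.cigar:
        if op in "=XM":
            m[rp:rp + n] = qp + np.arange(n)
            rp += n
            qp += n
        elif op == "D":
            m[rp:rp + n] = qp
            rp += n
        else:  # I, S
            qp += n
        if sentinel is None and rp == span and op in "=XMD":
            sentinel = qp
    m[span] = qp if sentinel is None else sentinel
    return m


def _allele_windows(ref_seq: str, position: int, alleles: Sequence[str],
                    window: int,
                    backbone: "Mapping[int, str] | None" = None,
                    ) -> tuple[int, int, list[tuple[str, str]]]:
    j = position - 1
    r0, r1 = max(j - window, 0), min(j + 1 + window, len(ref_seq))
    ctx = list(ref_seq[r0:r1])
    if backbone:
        # substitute the sample's homozygous calls at *other* positions so
        # each allele hypothesis is evaluated on the sample's own haplotype
        for p, base in backbone.items():
            if r0 + 1 <= p <= r1 and p != position:
                ctx[p - 1 - r0] = base
    left, right = "".join(ctx[:j - r0]), "".join(ctx[j - r0 + 1:])
    site_base = ctx[j - r0]
    variants = []
    for al in alleles:
        if al == "-":
            v = left + right
        elif al.startswith("+"):
            v = left + site_base + al[1:] + right
        else:
            v = left + al + right
        variants.append((al, v))
    return r0, r1, variants


def realigned_counts_multi(alignments: Sequence[AlignedRead], ref_seq: str,
                           sites: Mapping[int, Sequence[str]],
                           window: int = 20,
                           backbone: "Mapping[int, str] | None" = None,
                           ) -> dict[int, dict[str, int]]:
    """Realigned per-allele read counts for many sites in one pass.

    Builds one reference-to-query index map per alignment, then scores the
    read segment over each site window against one candidate haplotype
    window per allele; ties are ambiguous and counted for no allele.
    """
    prepared = {p: _allele_windows(ref_seq, p, als, window, backbone)
                for p, als in sites.items()}
    out = {p: {al: 0 for al in als} for p, als in sites.items()}
    for a in alignments:
        m = _ref_to_query_map(a)
        for p, (r0, r1, variants) in prepared.items():
            if not (a.ref_start <= r0 and r1 <= a.ref_end):
                continue
            q0 = int(m[r0 - a.ref_start])
            q1 = int(m[r1 - a.ref_start]) if r1 < a.ref_end else \
                int(m[a.ref_end - a.ref_start])
            seg = a.sequence[q0:q1]
            if not seg:
                continue
            best = []
            for al, v in variants:
                d = edlib.align(seg, v, mode="NW",
                                task="distance")["editDistance"]
                best.append((d, al))
            best.sort()
            if len(best) > 1 and best[0][0] == best[1][0]:
                continue
            out[p][best[0][1]] += 1
    return out


def realigned_site_counts(alignments: Sequence[AlignedRead], ref_seq: str,
                          position: int, alleles: Sequence[str],
                          window: int = 20) -> dict[str, int]:
    """Per-allele read counts at a single site from local realignment."""
    return realigned_counts_multi(alignments, ref_seq,
                                  {position: list(alleles)},
                                  window)[position]


def _allele_quality(count: int, depth: int, error_rate: float) -> float:
    """Phred-scaled binomial tail P(X >= count | depth, error_rate)."""
    p = stats.binom.sf(count - 1, depth, error_rate)
    return float(-10.0 * np.log10(max(p, 1e-300)))


def call_variants(pileup: Pileup, params: SnpParams | None = None,
                  alignments: Sequence[AlignedRead] | None = None,
                  ) -> list[SmallVariantCall]:
    """Emit pileup variant calls that pass the count/frequency/quality rules.

    At each position with depth >= ``min_depth``, every non-reference allele
    must reach ``min_count`` reads, frequency ``min_freq`` and site quality
    ``min_qual``.  Two qualifying alleles — or one plus a still-qualifying
    reference — make a het call.  By default only substitution alleles are
    called here (indels go through :func:`consensus_indels`; see
    ``SnpParams.call_indels``); with ``call_indels`` deletion columns and
    insertion events are called under the same rules, and multi-column
    deletions surface as runs of adjacent deletion calls.

    With ``alignments`` given, counts at every candidate site are refined
    by allele-aware local realignment (:func:`realign_allele`), removing
    the reference bias that raw pileup columns inherit from gap placement
    in noisy reads.
    """
    params = params or SnpParams()
    counts = pileup.counts
    depth = pileup.depth
    ref_codes = pileup.ref_codes
    alpha = "ACGT-"
    calls: list[SmallVariantCall] = []
    candidates = np.flatnonzero(depth >= params.min_depth)
    # cheap pre-screen: some non-reference allele reaches the count floor
    nonref = counts.copy()
    nonref[ref_codes, np.arange(len(pileup.ref_seq))] = 0
    candidates = candidates[nonref[:, candidates].max(axis=0)
                            >= params.min_count]
    site_tests: dict[int, list[str]] = {}
    for j in candidates:
        ref_a = alpha[ref_codes[j]]
        raw = {alpha[i]: int(counts[i, j])
               for i in range(5 if params.call_indels else 4)}
        cand_alts = sorted((al for al, c in raw.items()
                            if al != ref_a and c >= params.min_count),
                           key=lambda al: (-raw[al], al))[:2]
        if cand_alts:
            site_tests[int(j)] = [ref_a] + cand_alts
    def evaluate(refined) -> list[SmallVariantCall]:
        out: list[SmallVariantCall] = []
        for j, tested in site_tests.items():
            ref_a, cand_alts = tested[0], tested[1:]
            if refined is not None:
                site_counts = refined[j + 1]
                d = sum(site_counts.values())
            else:
                site_counts = {al: int(counts[alpha.index(al), j])
                               for al in tested}
                d = int(depth[j])
            if d < params.min_depth:
                continue
            quals = {}
            for al in cand_alts:
                c = site_counts[al]
                if c < params.min_count or c / d < params.min_freq:
                    continue
                q = _allele_quality(c, d, params.error_rate)
                if q >= params.min_qual:
                    quals[al] = (c, q)
            if not quals:
                continue
            top = sorted(quals, key=lambda al: (-quals[al][0], al))[:2]
            ref_count = site_counts[ref_a]
            if len(top) >= 2:
                alleles = tuple(sorted(top[:2]))
                zyg = "het"
            elif ref_count >= params.min_count and \
                    ref_count / d >= params.min_freq:
                alleles = tuple(sorted((ref_a, top[0])))
                zyg = "het"
            else:
                alleles = (top[0],)
                zyg = "hom"
            kind = "DEL" if "-" in quals and "-" in alleles else "SNP"
            out.append(SmallVariantCall(
                ref_id=pileup.ref_id, position=j + 1, ref_allele=ref_a,
                alleles=alleles,
                counts={al: site_counts.get(al, 0) for al in
                        dict.fromkeys(alleles + (ref_a,))},
                zygosity=zyg, quality=min(q for _, q in quals.values()),
                kind=kind))
        return out

    tested_sites = {j + 1: als for j, als in site_tests.items()}
    if alignments is None:
        calls.extend(evaluate(None))
    else:
        calls.extend(evaluate(realigned_counts_multi(
            alignments, pileup.ref_seq, tested_sites)))
    # insertion events
    for col, seqs in sorted(pileup.insertions.items()) if \
            params.call_indels else []:
        span = int(depth[col]) if col < len(pileup.ref_seq) else \
            int(depth[len(pileup.ref_seq) - 1])
        if span < params.min_depth:
            continue
        c = sum(seqs.values())
        if c < params.min_count or c / span < params.min_freq:
            continue
        q = _allele_quality(c, span, params.error_rate)
        if q < params.min_qual:
            continue
        best_seq = min(s for s, n in seqs.items()
                       if n == max(seqs.values()))
        zyg = "het" if (span - c) >= params.min_count and \
            (span - c) / span >= params.min_freq else "hom"
        alleles = (f"+{best_seq}",) if zyg == "hom" else \
            tuple(sorted(("-", f"+{best_seq}")))
        calls.append(SmallVariantCall(
            ref_id=pileup.ref_id, position=col + 1, ref_allele="-",
            alleles=alleles, counts={f"+{best_seq}": c, "-": span - c},
            zygosity=zyg, quality=q, kind="INS"))
    calls.sort(key=lambda c: (c.position, c.kind))
    return calls


def homopolymer_filter(calls: Sequence[SmallVariantCall],
                       ref: HomoeologReference | str,
                       run_len: int = 4) -> list[SmallVariantCall]:
    """Flag calls inside or immediately adjacent to a homopolymer run.

    Single-molecule sequencers inflate indel errors in single-base runs;
    flagged calls keep their record but are excluded from haplotype phasing
    and grouping.  Idempotent: flags are recomputed, never stacked.
    """
    ref_seq = ref.sequence if isinstance(ref, HomoeologReference) else ref
    mask = _homopolymer_mask(_to_codes(ref_seq), run_len)
    padded = np.zeros(mask.size + 2, dtype=bool)
    padded[1:-1] = mask
    near = padded[:-2] | padded[1:-1] | padded[2:]  # inside or adjacent
    out = []
    for c in calls:
        j = c.position - 1
        flagged = bool(near[j]) if 0 <= j < mask.size else False
        out.append(replace(c, filter="homopolymer" if flagged else "pass"))
    return out


def consensus_indels(consensus: str, ref: HomoeologReference | str,
                     min_len: int = 1, max_len: int = 29,
                     ref_id: str = "ref") -> list[SmallVariantCall]:
    """Indels below the SV threshold, from consensus-to-reference alignment.

    The consensus is globally aligned to the reference; gap runs with length
    in [min_len, max_len] become hom indel calls (longer gaps belong to the
    SV caller).  An empty consensus yields no calls.
    """
    if not consensus:
        return []
    from .homeoalign import AlignParams, _consolidate, _parse_cigar

    ref_seq = ref.sequence if isinstance(ref, HomoeologReference) else ref
    res = edlib.align(consensus, ref_seq, mode="NW", task="path")
    # small gaps smear under path degeneracy just like large ones
    cigar = _consolidate(_parse_cigar(res["cigar"]), consensus, ref_seq, 0,
                         AlignParams(anchor_min=20, consolidate_min=4))
    calls = []
    rp = qp = 0
    for op, n in cigar:
        if op in "=XM":
            rp += n
            qp += n
        elif op == "D":  # present in reference, absent from consensus
            if min_len <= n <= max_len:
                calls.append(SmallVariantCall(
                    ref_id=ref_id, position=rp + 1,
                    ref_allele=ref_seq[rp:rp + n], alleles=("-",),
                    counts={}, zygosity="hom", quality=float("nan"),
                    kind="DEL"))
            rp += n
        elif op == "I":
            if min_len <= n <= max_len:
                calls.append(SmallVariantCall(
                    ref_id=ref_id, position=rp + 1, ref_allele="-",
                    alleles=(f"+{consensus[qp:qp + n]}",), counts={},
                    zygosity="hom", quality=float("nan"), kind="INS"))
            qp += n
    return calls


def indel_shadow_filter(snp_calls: Sequence[SmallVariantCall],
                        indel_calls: Sequence[SmallVariantCall],
                        distance: int = 2) -> list[SmallVariantCall]:
    """Mask substitution calls that shadow an adjacent variant.

    Reads carrying a real variant produce ambiguous local alignments at
    the neighbouring columns, where the shifted base can masquerade as a
    substitution.  Two shadow classes are flagged ``indel_shadow``:

    * a SNP call within ``distance`` of an indel call in the same sample
      whose alternate allele occurs in the indel's inserted/deleted
      sequence, and
    * a *heterozygous* SNP call within ``distance`` of a *homozygous* SNP
      call whose non-reference allele equals that call's allele (the
      shifted-substitution phantom arising in repeat context).
    """
    shadows: list[tuple[int, int, set[str]]] = []
    for c in indel_calls:
        if c.kind == "DEL":
            span = (c.position, c.position + max(len(c.ref_allele), 1) - 1)
            bases = set(c.ref_allele)
        elif c.kind == "INS":
            span = (c.position - 1, c.position)
            bases = {b for al in c.alleles if al.startswith("+")
                     for b in al[1:]}
        else:
            continue
        shadows.append((span[0] - distance, span[1] + distance, bases))
    hom_snps = [(c.position, c.alleles[0]) for c in snp_calls
                if c.kind == "SNP" and c.zygosity == "hom"]
    out = []
    for c in snp_calls:
        flagged = c.kind == "SNP" and any(
            lo <= c.position <= hi and set(c.alleles) & bases
            for lo, hi, bases in shadows)
        if not flagged and c.kind == "SNP" and c.zygosity == "het":
            alts = set(c.alleles) - {c.ref_allele}
            flagged = any(p != c.position
                          and abs(p - c.position) <= distance and al in alts
                          for p, al in hom_snps)
        out.append(replace(c, filter="indel_shadow") if flagged else c)
    return out


def variant_positions(calls: Sequence[SmallVariantCall]) -> set[int]:
    """Distinct 1-based reference positions covered by a call set.

    A deletion of L bases covers L positions (each deleted column is its
    own polymorphic site, the convention of per-site genotype tables);
    SNPs and insertions cover one.
    """
    out: set[int] = set()
    for c in calls:
        if c.kind == "DEL" and c.ref_allele not in ("", "-"):
            out.update(range(c.position, c.position + len(c.ref_allele)))
        else:
            out.add(c.position)
    return out


def write_vcf(calls_by_sample: Mapping[str, Sequence[SmallVariantCall]],
              refs: Mapping[str, HomoeologReference | str], path) -> None:
    """Minimal multi-sample VCF 4.2; amplicon coordinates go to INFO/AMPPOS."""
    samples = sorted(calls_by_sample)
    keyed: dict[tuple, dict[str, SmallVariantCall]] = {}
    for s in samples:
        for c in calls_by_sample[s]:
            keyed.setdefault((c.ref_id, c.position, c.kind), {})[s] = c
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for h, r in sorted(refs.items()):
            ln = len(r.sequence if isinstance(r, HomoeologReference) else r)
            fh.write(f"##contig=<ID={h},length={ln}>\n")
        fh.write('##INFO=<ID=AMPPOS,Number=1,Type=Integer,'
                 'Description="1-based position from the forward primer 3-prime end">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for (ref_id, pos, kind), per in sorted(keyed.items()):
            any_call = next(iter(per.values()))
            ref_seq = refs[ref_id]
            ref_seq = ref_seq.sequence if isinstance(ref_seq,
                                                     HomoeologReference) else ref_seq
            if kind == "SNP":
                vcf_pos, ref_al = pos, ref_seq[pos - 1]
                alts = sorted({al for c in per.values() for al in c.alleles
                               if al not in ("-", ref_al)})
            elif kind == "DEL":  # anchor with the previous base
                vcf_pos = max(pos - 1, 1)
                ref_al = ref_seq[vcf_pos - 1:pos]
                alts = [ref_seq[vcf_pos - 1]]
            else:  # INS
                vcf_pos = max(pos - 1, 1)
                ref_al = ref_seq[vcf_pos - 1]
                ins = sorted({al[1:] for c in per.values()
                              for al in c.alleles if al.startswith("+")})
                alts = [ref_al + i for i in ins]
            gts = []
            for s in samples:
                c = per.get(s)
                if c is None:
                    gts.append("./.")
                    continue
                def idx(al: str) -> int:
                    if kind == "SNP":
                        return 0 if al == ref_al else alts.index(al) + 1
                    if al in ("-",) and kind == "DEL":
                        return 1
                    if al.startswith("+"):
                        return alts.index(ref_al + al[1:]) + 1
                    return 0
                ids = sorted(idx(a) for a in c.alleles)
                if len(ids) == 1:
                    ids = ids * 2
                gts.append("/".join(map(str, ids)))
            qual = max((c.quality for c in per.values()
                        if np.isfinite(c.quality)), default=30.0)
            filt = "PASS" if all(c.filter == "pass" for c in per.values()) \
                else "homopolymer"
            fh.write(f"{ref_id}\t{vcf_pos}\t.\t{ref_al}\t{','.join(alts)}\t"
                     f"{qual:.0f}\t{filt}\tAMPPOS={pos}\tGT\t"
                     + "\t".join(gts) + "\n")
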