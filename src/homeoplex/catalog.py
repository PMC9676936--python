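"""Curated catalog of known VRN1 polymorphisms used to build truth panels.

The three homoeologous VRN1 genes of hexaploid wheat (VRN-A1 on 5A, VRN-B1
on 5B, VRN-D1 on 5D) carry a well-characterised set of alleles: the spring
alleles are marked by structural variants (a 231 bp promoter insertion in
Vrn-A1a, a 6,851 bp first-intron deletion in Vrn-B1a, a 37 bp deletion in
Vrn-B1b, an 838 bp first-intron tandem duplication in Vrn-B1f, a 163 bp
first-intron insertion in Vrn-D1x and a 17 bp deletion in vrn-D1r), while
the winter cultivars differ by a catalog of SNPs and 1-3 bp indels that
partition them into genotype and haplotype groups, with heterozygous sites
whose allele dosage reflects VRN-A1 copy number.

Positions are 1-based on the synthetic reference amplicons, counted from the
base after the forward primer's 3' end.  SNP/indel coordinates follow the
published site lists; SV start coordinates are synthetic placements chosen
consistently with the gene architecture (all first-intron events inside
intron 1, the large VRN-B1 deletion spanning the two sites it erases, the
duplication spanning the two duplication-induced heterozygous sites).

This module contains data plus thin builders; all mechanics live in
:mod:`homeoplex.synthgen`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .synthgen import (AlleleEdit, CultivarGenotype, HomoeologReference,
                       TemplateCopy, reverse_complement, _to_str)

__all__ = [
    "SV_ALLELES",
    "VRN_A1_POSITIONS", "VRN_A1_GROUP_ALLELES", "VRN_A1_HET_EXCLUDED_FROM_PHASING",
    "VRN_A1_DOSAGE_SITE", "VRN_B1_POSITIONS", "VRN_B1_HAPLOTYPES",
    "VRN_D1_VARIANTS", "vrn_a1_matrix", "vrn_b1_matrix", "vrn_d1_matrix",
    "haplotype_edits", "vrn_a1_genotype", "sv_genotype", "table4_scenario",
    "prepare_reference", "vrn_a1_het_sites",
]

_IUPAC = {"Y": ("C", "T"), "S": ("C", "G"), "R": ("A", "G"),
          "K": ("G", "T"), "W": ("A", "T"), "M": ("A", "C")}


def _foldback(seed: int, total: int) -> str:
    """Deterministic foldback-repeat-like sequence (s + pivot + revcomp(s))."""
    rng = np.random.default_rng(seed)
    half = (total - 1) // 2
    s = _to_str(rng.integers(0, 4, half, dtype=np.uint8))
    pivot = _to_str(rng.integers(0, 4, total - 2 * half, dtype=np.uint8))
    return s + pivot + reverse_complement(s)


def _random_insert(seed: int, total: int) -> str:
    rng = np.random.default_rng(seed)
    return _to_str(rng.integers(0, 4, total, dtype=np.uint8))


# --- structural-variant alleles -------------------------------------------
SV_ALLELES: dict[str, tuple[str, AlleleEdit]] = {
    # allele -> (homoeolog, edit)
    "Vrn-A1a": ("A", AlleleEdit("INS", 350, 231, _foldback(2022, 231))),
    "Vrn-B1f": ("B", AlleleEdit("DUP", 8650, 838)),
    "Vrn-B1a": ("B", AlleleEdit("DEL", 1501, 6851)),
    "Vrn-B1b": ("B", AlleleEdit("DEL", 8400, 37)),
    "Vrn-D1x": ("D", AlleleEdit("INS", 1600, 163, _random_insert(2023, 163))),
    "vrn-D1r": ("D", AlleleEdit("DEL", 3000, 17)),
}

# --- VRN-A1 SNP/indel catalog ---------------------------------------------
# 51 polymorphic sites; the reference backbone carries the GT3 alleles.
VRN_A1_POSITIONS: tuple[int, ...] = (
    147, 244, 381, 1781, 1890, 2066, 3184, 3296, 3298, 3386, 3393, 3408,
    3431, 3459, 3463, 3701, 3999, 4138, 4646, 4703, 4740, 4757, 5270, 5634,
    5722, 5801, 5928, 5932, 6129, 6160, 6568, 6907, 6978, 7468, 7625, 7738,
    8036, 8201, 8266, 9062, 9736, 10201, 10802, 10909, 11109, 11234, 11235,
    11236, 11344, 11639, 11735,
)

# per-group allele strings over the 51 sites ("-" = no base; IUPAC = het)
VRN_A1_GROUP_ALLELES: dict[str, str] = {
    "GT1": "ATCTAACTGCCCGGCATGCCTGGGCGCAAAGCCCCTTCTTATTTCG---AC",
    "GT2": "AGCTTGCCTTTTGCTGGGTTTGGAGTCGGATCTGCGCCCTGCGCCAAC-AC",
    "GT3": "GGC-AAGTGCCTAGCGGGCCGGTGGGGAGTTTCGAGCGCGGCGTCAACA-T",
    "GT4": "GGC-AAGTGCCTAGCGGGCCGGTGGGGAGTTTCGAGCGCGGCGTYAACA-T",
    "GT5": "GGS-AAGTGCCTAGCGGGCCGRTGGGGAGTTTCGAGCGCGGCGTYAACA-T",
}
# GT6 = GT4 plus a G/A het at site 18 (position 4138)
_gt6 = list(VRN_A1_GROUP_ALLELES["GT4"])
_gt6[17] = "R"
VRN_A1_GROUP_ALLELES["GT6"] = "".join(_gt6)
del _gt6

VRN_A1_HAPLOTYPE_GROUPS = {"GT1": "Hap1", "GT2": "Hap2", "GT3": "Hap3"}
# het site between G/C repeats that short-range signal cannot resolve;
# excluded from phasing input
VRN_A1_HET_EXCLUDED_FROM_PHASING: tuple[int, ...] = (381,)
VRN_A1_DOSAGE_SITE = 11109  # exon-4 C/T site whose dosage tracks copy number

# --- VRN-B1 haplotype catalog ---------------------------------------------
VRN_B1_POSITIONS: tuple[int, ...] = (7505, 8351, 8615, 9080, 9387, 10971)
# matrix entries: base, "X/Y" het, or "-" (erased by the 6,851 bp deletion)
VRN_B1_HAPLOTYPES: dict[str, tuple[str, ...]] = {
    "Hap1": ("G", "G", "G", "T", "A", "G"),
    "Hap2": ("A", "A", "G", "T/C", "A/C", "A"),
    "Hap3": ("G", "G", "G", "T", "A", "A"),
    "Hap4": ("G", "G", "A", "T", "A", "G"),
    "Hap5": ("-", "-", "G", "T", "A", "G"),
}
VRN_B1_REF_ALLELES = VRN_B1_HAPLOTYPES["Hap1"]

# --- VRN-D1 variants --------------------------------------------------------
VRN_D1_VARIANTS: dict[str, AlleleEdit] = {
    "ins163": SV_ALLELES["Vrn-D1x"][1],
    "del17": SV_ALLELES["vrn-D1r"][1],
    "snp5607": AlleleEdit("SNP", 5607, 1, "G"),
}
VRN_D1_SNP_REF = "A"


# ---------------------------------------------------------------------------
# printed matrices (used directly for grouping)
# ---------------------------------------------------------------------------

def _expand(symbol: str) -> str:
    if symbol in _IUPAC:
        return "/".join(sorted(_IUPAC[symbol]))
    return symbol


def vrn_a1_matrix() -> pd.DataFrame:
    """Genotype-group x site matrix of VRN-A1 alleles (hets as 'X/Y')."""
    rows = {gt: [_expand(a) for a in alleles]
            for gt, alleles in VRN_A1_GROUP_ALLELES.items()}
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=list(VRN_A1_POSITIONS))


def vrn_b1_matrix() -> pd.DataFrame:
    return pd.DataFrame.from_dict(VRN_B1_HAPLOTYPES, orient="index",
                                  columns=list(VRN_B1_POSITIONS))


def vrn_d1_matrix() -> pd.DataFrame:
    """Presence/absence matrix of the three VRN-D1 variants, one row per
    observed configuration (intact, +ins163, +del17, +snp5607)."""
    rows = {
        "intact": [0, 0, 0],
        "ins163": [1, 0, 0],
        "del17": [0, 1, 0],
        "snp5607": [0, 0, 1],
    }
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=list(VRN_D1_VARIANTS))


# ---------------------------------------------------------------------------
# genotype builders
# ---------------------------------------------------------------------------

def haplotype_edits(alleles: str) -> tuple[AlleleEdit, ...]:
    """Edits turning the reference (GT3) backbone into a haplotype.

    ``alleles`` is a 51-character string over the catalog sites (no IUPAC
    codes: a haplotype is fully resolved).  Adjacent deleted sites merge
    into a single deletion edit.
    """
    ref = VRN_A1_GROUP_ALLELES["GT3"]
    if len(alleles) != len(ref):
        raise ValueError("allele string must cover all catalog sites")
    edits: list[AlleleEdit] = []
    i = 0
    while i < len(ref):
        pos, a, r = VRN_A1_POSITIONS[i], alleles[i], ref[i]
        if a == r:
            i += 1
            continue
        if r == "-":  # site absent from the reference -> insertion allele
            edits.append(AlleleEdit("INS", pos, len(a), a))
            i += 1
        elif a == "-":  # deletion allele; merge a run of adjacent sites
            j = i
            while (j + 1 < len(ref) and alleles[j + 1] == "-"
                   and ref[j + 1] != "-"
                   and VRN_A1_POSITIONS[j + 1] == VRN_A1_POSITIONS[j] + 1):
                j += 1
            edits.append(AlleleEdit("DEL", pos, VRN_A1_POSITIONS[j] - pos + 1))
            i = j + 1
        else:
            edits.append(AlleleEdit("SNP", pos, 1, a))
            i += 1
    return tuple(edits)


def _hap(alleles_by_site: dict[int, str]) -> str:
    """A haplotype string = GT3 backbone with specific sites overridden."""
    out = list(VRN_A1_GROUP_ALLELES["GT3"])
    for pos, allele in alleles_by_site.items():
        out[VRN_A1_POSITIONS.index(pos)] = allele
    return "".join(out)


# resolved haplotypes over (SNP3@381, SNP18@4138, SNP22@4757, SNP45@11109)
VRN_A1_HAPLOTYPE_STRINGS: dict[str, str] = {
    "Hap1": VRN_A1_GROUP_ALLELES["GT1"],
    "Hap2": VRN_A1_GROUP_ALLELES["GT2"],
    "Hap3": VRN_A1_GROUP_ALLELES["GT3"],
    "Hap4": _hap({11109: "T"}),
    "Hap5": _hap({381: "G", 4757: "A"}),
    "Hap6": _hap({381: "G", 4757: "A", 11109: "T"}),
    "Hap7": _hap({4138: "A"}),
    "Hap8": _hap({4138: "A", 11109: "T"}),
}

# genotype group -> list of (haplotype, copy multiplicity); the dosage
# configurations mirror the published copy-number table (a skewed 2:1 T:C
# dosage for the three-copy groups, balanced otherwise)
VRN_A1_GROUP_COPIES: dict[str, list[tuple[str, int]]] = {
    "GT1": [("Hap1", 1)],
    "GT2": [("Hap2", 1)],
    "GT3": [("Hap3", 1)],
    "GT4": [("Hap4", 2), ("Hap3", 1)],           # cluster 3: three copies
    "GT4-cluster2": [("Hap4", 1), ("Hap3", 1)],  # cluster 2: two copies
    "GT5": [("Hap3", 1), ("Hap4", 1), ("Hap5", 1), ("Hap6", 1)],
    "GT6": [("Hap3", 1), ("Hap4", 1), ("Hap7", 1), ("Hap8", 1)],
}


def vrn_a1_genotype(group: str, cultivar_id: str | None = None) -> CultivarGenotype:
    """Cultivar genotype for one VRN-A1 genotype group.

    Copy weights are normalised to sum to one, so ``mean_coverage`` in
    :func:`homeoplex.synthgen.simulate_panel` is per-cultivar coverage and
    the allele dosage at heterozygous sites equals the copy proportions.
    """
    spec = VRN_A1_GROUP_COPIES[group]
    total = sum(m for _, m in spec)
    # expand multiplicity into distinct physical copies with equal weights
    expanded: list[TemplateCopy] = []
    for h, m in spec:
        e = haplotype_edits(VRN_A1_HAPLOTYPE_STRINGS[h])
        for k in range(m):
            expanded.append(TemplateCopy(edits=e, haplotype=h, weight=1.0 / total))
    return CultivarGenotype(cultivar_id or group, {"A": expanded})


def sv_genotype(cultivar_id: str, alleles: list[str],
                homoeologs: tuple[str, ...] = ("A", "B", "D"),
                ) -> CultivarGenotype:
    """Single-copy genotype carrying the named SV alleles, intact elsewhere."""
    per_hom: dict[str, list[AlleleEdit]] = {h: [] for h in homoeologs}
    for name in alleles:
        hom, edit = SV_ALLELES[name]
        per_hom.setdefault(hom, []).append(edit)
    copies = {h: [TemplateCopy(edits=tuple(sorted(e, key=lambda x: x.position)),
                               haplotype=("+".join(alleles) or "intact"))]
              for h, e in per_hom.items()}
    return CultivarGenotype(cultivar_id, copies)


def table4_scenario() -> list[CultivarGenotype]:
    """The three copy-number configurations of the published comparison:
    three copies (2 haplotypes, skewed dosage), two copies (2 haplotypes,
    balanced), four copies (4 haplotypes)."""
    return [
        vrn_a1_genotype("GT4", "cv_three_copies"),
        vrn_a1_genotype("GT4-cluster2", "cv_two_copies"),
        vrn_a1_genotype("GT6", "cv_four_copies"),
    ]


# ---------------------------------------------------------------------------
# reference preparation
# ---------------------------------------------------------------------------

def _sanitize_window(seq: list[str], pos0: int, locked: set[int],
                     radius: int = 5) -> None:
    """Break single-base runs of >= 3 around pos0 so the site is never inside
    or adjacent to a homopolymer run of >= 4.  Locked positions (catalog
    sites, planted motifs) are never rewritten."""
    lo = max(0, pos0 - radius)
    hi = min(len(seq), pos0 + radius + 1)
    for i in range(lo + 2, hi):
        if seq[i] == seq[i - 1] == seq[i - 2]:
            if i in locked:
                continue
            for b in "ACGT":
                nxt = seq[i + 1] if i + 1 < len(seq) else ""
                if b != seq[i - 1] and b != nxt:
                    seq[i] = b
                    break


def prepare_reference(ref: HomoeologReference,
                      sites: dict[int, str],
                      locked_spans: tuple[tuple[int, int], ...] = (),
                      ) -> HomoeologReference:
    """Install catalog site contexts on a generated reference.

    For every 1-based site, the reference base is set to the catalog's
    backbone allele (sites whose backbone allele is ``-`` only get their
    context sanitised), and the +/-5 bp neighbourhood is rewritten so no
    homopolymer run of four or more touches the site — variant calls at
    catalog sites must never be casualties of the homopolymer exclusion
    rule, which models a basecaller artifact, not real variation.
    """
    seq = list(ref.sequence)
    locked: set[int] = set()
    for s, e in locked_spans:
        locked.update(range(s - 1, e))
    for pos in sites:
        locked.add(pos - 1)
    for pos, base in sites.items():
        if base != "-":
            seq[pos - 1] = base
    for pos in sites:
        _sanitize_window(seq, pos - 1, locked)
    return HomoeologReference(ref.id, "".join(seq), ref.promoter_len,
                              dict(ref.feature_map))


# Indel catalog sites need an unambiguous local context: an insertion (or
# deletion) inside a repeat left-aligns to a different coordinate than the
# printed one.  Positions here must not carry the forbidden base.
_A1_INDEL_CONTEXT: tuple[tuple[int, frozenset], ...] = (
    (1780, frozenset("T")), (1782, frozenset("T")),   # 1 bp T insertion
    (11233, frozenset("A")),                          # AC deletion after an A run
    (11343, frozenset("A")), (11345, frozenset("A")),  # 1 bp A deletion
    (11638, frozenset("A")), (11640, frozenset("A")),  # 1 bp A insertion
)


def _enforce_context(ref: HomoeologReference,
                     rules: tuple[tuple[int, frozenset], ...],
                     locked: set[int]) -> HomoeologReference:
    seq = list(ref.sequence)
    for pos, forbidden in rules:
        i = pos - 1
        if i in locked or seq[i] not in forbidden:
            continue
        neighbours = {seq[i - 1] if i > 0 else "",
                      seq[i + 1] if i + 1 < len(seq) else ""}
        seq[i] = next(b for b in "ACGT"
                      if b not in forbidden and b not in neighbours)
    return HomoeologReference(ref.id, "".join(seq), ref.promoter_len,
                              dict(ref.feature_map))


def _replant_motifs(ref: HomoeologReference) -> HomoeologReference:
    """Fix the conserved G4 motifs at their nominal coordinates.

    Indel divergence shifts the ancestor-planted motifs off their printed
    positions; re-writing them here restores exact coordinates in every
    homoeolog (the motifs are conserved across the three genes).  The
    boundary bases are forced non-G so a flanking G cannot extend a motif
    tract into a homopolymer run of four.
    """
    from .synthgen import G4_MOTIF, G4_PLANT_POSITIONS
    seq = list(ref.sequence)
    for p in G4_PLANT_POSITIONS:
        i = p - 1
        seq[i:i + len(G4_MOTIF)] = list(G4_MOTIF)
        for j in (i - 1, i + len(G4_MOTIF)):
            if 0 <= j < len(seq) and seq[j] == "G":
                nbrs = {seq[j - 1] if j > 0 else "",
                        seq[j + 1] if j + 1 < len(seq) else ""}
                seq[j] = next(b for b in "ACT" if b not in nbrs)
    return HomoeologReference(ref.id, "".join(seq), ref.promoter_len,
                              dict(ref.feature_map))


def prepare_panel(refs: tuple[HomoeologReference, ...],
                  ) -> dict[str, HomoeologReference]:
    """Prepare the A/B/D references with all catalog site contexts installed."""
    from .synthgen import G4_MOTIF, G4_PLANT_POSITIONS
    motif_spans = tuple((p, p + len(G4_MOTIF) - 1) for p in G4_PLANT_POSITIONS)
    a, b, d = (_replant_motifs(r) for r in refs)
    ref_row = VRN_A1_GROUP_ALLELES["GT3"]
    a_sites = {pos: ref_row[i] for i, pos in enumerate(VRN_A1_POSITIONS)}
    b_sites = dict(zip(VRN_B1_POSITIONS, VRN_B1_REF_ALLELES))
    d_sites = {5607: VRN_D1_SNP_REF}
    a_ref = _enforce_context(prepare_reference(a, a_sites, motif_spans),
                             _A1_INDEL_CONTEXT,
                             {p - 1 for p in VRN_A1_POSITIONS})
    return {
        "A": a_ref,
        "B": prepare_reference(b, b_sites, motif_spans),
        "D": prepare_reference(d, d_sites, motif_spans),
    }


def vrn_a1_het_sites(group: str) -> tuple[int, ...]:
    """Heterozygous catalog sites of a genotype group, in position order,
    excluding sites unresolvable from long reads (the G/C-repeat site)."""
    alleles = VRN_A1_GROUP_ALLELES[group]
    sites = [pos for pos, a in zip(VRN_A1_POSITIONS, alleles)
             if a in _IUPAC and pos not in VRN_A1_HET_EXCLUDED_FROM_PHASING]
    return tuple(sites)
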