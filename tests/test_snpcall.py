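"""Pileup construction, SNP calling filters, homopolymer flag, indels."""

import numpy as np
import pytest

from homeoplex import catalog as cat
from homeoplex import synthgen as sg
from homeoplex.homeoalign import align_and_assign, align_to_references, \
    assign_homoeolog, reference_guided_consensus
from homeoplex.phasecn import read_allele_at
from homeoplex.snpcall import (SnpParams, build_pileup, call_variants,
                               consensus_indels, homopolymer_filter,
                               variant_positions,
                               indel_shadow_filter)
from homeoplex.synthgen import AlleleEdit, ErrorModel

from helpers import AMPLICON_ONLY, planted_a1_sites


def _aligned(reads, ref):
    return [assign_homoeolog(align_to_references(r, {"A": ref}))
            for r in reads]


def _pileup_from(template, ref, n):
    return build_pileup(_aligned([(f"r{i}", template) for i in range(n)],
                                 ref), ref, ref_id="A")


class TestBuildPileup:
    def test_identical_reads_single_allele(self, refs):
        ref = refs["A"].sequence
        pile = _pileup_from(ref[1000:3000], ref, 10)
        covered = slice(1000, 3000)
        assert (pile.depth[covered] == 10).all()
        assert (pile.counts[:, covered].max(axis=0) == 10).all()

    def test_mixed_site_counts(self, refs):
        ref = refs["A"].sequence
        pos = 2000
        alt = "T" if ref[pos - 1] != "T" else "C"
        edited = sg.apply_allele(ref, [AlleleEdit("SNP", pos, 1, alt)])
        reads = [(f"t{i}", edited[1000:3000]) for i in range(7)] + \
                [(f"c{i}", ref[1000:3000]) for i in range(3)]
        pile = build_pileup(_aligned(reads, ref), ref, ref_id="A")
        alpha = "ACGT-"
        assert pile.counts[alpha.index(alt), pos - 1] == 7
        assert pile.counts[alpha.index(ref[pos - 1]), pos - 1] == 3

    def test_column_sums_match_per_read_recount(self, refs):
        """Pileup tallies equal an independent per-read allele extraction."""
        ref = refs["A"].sequence[:3000]
        em = ErrorModel(**AMPLICON_ONLY)
        gt = sg.CultivarGenotype("cv", {"A": [sg.TemplateCopy()]})
        reads, _ = sg.simulate_panel([gt], {"A": ref}, 15, em,
                                     sg.make_barcodes(4), seed=3,
                                     full_length_prob=1.0)
        alns = align_and_assign(reads, {"A": ref})
        pile = build_pileup(alns, ref, ref_id="A")
        rng = np.random.default_rng(0)
        alpha = "ACGT-"
        for pos in rng.integers(50, 2950, 30):
            counts = {al: 0 for al in alpha}
            for a in alns:
                al = read_allele_at(a, int(pos))
                if al is not None:
                    counts[al] += 1
            assert [counts[al] for al in alpha] == \
                list(pile.counts[:, pos - 1])


class TestCallVariants:
    def test_low_count_alt_filtered(self, refs):
        ref = refs["A"].sequence
        pos = 2500
        alt = "T" if ref[pos - 1] != "T" else "C"
        edited = sg.apply_allele(ref, [AlleleEdit("SNP", pos, 1, alt)])
        reads = [(f"t{i}", edited[2000:4000]) for i in range(2)] + \
                [(f"c{i}", ref[2000:4000]) for i in range(98)]
        pile = build_pileup(_aligned(reads, ref), ref, ref_id="A")
        assert call_variants(pile) == []

    def test_skewed_het_called(self, refs):
        ref = refs["A"].sequence
        pos = 2500
        alt = "T" if ref[pos - 1] != "T" else "C"
        edited = sg.apply_allele(ref, [AlleleEdit("SNP", pos, 1, alt)])
        reads = [(f"t{i}", edited[2000:4000]) for i in range(70)] + \
                [(f"c{i}", ref[2000:4000]) for i in range(30)]
        pile = build_pileup(_aligned(reads, ref), ref, ref_id="A")
        calls = call_variants(pile)
        assert len(calls) == 1
        c = calls[0]
        assert c.position == pos and c.zygosity == "het"
        assert set(c.alleles) == {ref[pos - 1], alt}

    def test_all_reference_pileup_no_calls(self, refs):
        ref = refs["A"].sequence
        pile = _pileup_from(ref[:4000], ref, 20)
        assert call_variants(pile) == []

    def test_below_min_depth_not_called(self, refs):
        ref = refs["A"].sequence
        pos = 2500
        alt = "T" if ref[pos - 1] != "T" else "C"
        edited = sg.apply_allele(ref, [AlleleEdit("SNP", pos, 1, alt)])
        pile = _pileup_from(edited[2000:4000], ref, 10)  # depth 10 < 11
        assert call_variants(pile) == []

    def test_zero_false_het_on_homozygous_error_free(self, refs):
        ref = refs["A"].sequence
        edits = [AlleleEdit("SNP", p, 1, "A" if ref[p - 1] != "A" else "G")
                 for p in (1500, 4200, 9000)]
        edited = sg.apply_allele(ref, edits)
        pile = _pileup_from(edited, ref, 30)
        calls = call_variants(pile)
        assert {c.position for c in calls} == {1500, 4200, 9000}
        assert all(c.zygosity == "hom" for c in calls)


class TestHomopolymerFilter:
    def test_flags_match_exhaustive_run_scan(self, refs):
        """Filter decisions equal a brute-force run-length scan."""
        ref = refs["A"].sequence[:6000]
        from homeoplex.snpcall import SmallVariantCall
        calls = [SmallVariantCall("A", p, ref[p - 1], ("A",), {}, "hom",
                                  50.0, "SNP")
                 for p in range(2, 6000, 7) if ref[p - 1] != "A"]
        flagged = homopolymer_filter(calls, ref, run_len=4)
        for c in flagged:
            j = c.position - 1
            inside = False
            for s in range(max(0, j - 4), min(len(ref) - 3, j + 2)):
                run = ref[s:s + 4]
                if len(set(run)) == 1:
                    if s - 1 <= j <= s + 4:  # inside or adjacent
                        # extend to the full run for the adjacency check
                        e = s + 4
                        while e < len(ref) and ref[e] == ref[s]:
                            e += 1
                        b = s
                        while b > 0 and ref[b - 1] == ref[s]:
                            b -= 1
                        if b - 1 <= j <= e:
                            inside = True
            assert (c.filter == "homopolymer") == inside

    def test_idempotent(self, refs):
        ref = refs["A"].sequence
        pile = _pileup_from(
            sg.apply_allele(ref, [AlleleEdit("SNP", 2500, 1,
                                             "A" if ref[2499] != "A"
                                             else "G")]), ref, 20)
        once = homopolymer_filter(call_variants(pile), ref)
        twice = homopolymer_filter(once, ref)
        assert once == twice


class TestConsensusIndels:
    def test_seventeen_base_deletion(self, refs):
        cons = sg.apply_allele(refs["D"], [AlleleEdit("DEL", 3000, 17)])
        calls = consensus_indels(cons, refs["D"], ref_id="D")
        assert [(c.kind, c.position, len(c.ref_allele)) for c in calls] == \
            [("DEL", 3000, 17)]

    def test_identical_consensus_empty(self, refs):
        assert consensus_indels(refs["D"].sequence, refs["D"]) == []

    def test_single_base_deletion(self, refs):
        cons = sg.apply_allele(refs["A"], [AlleleEdit("DEL", 11344, 1)])
        calls = consensus_indels(cons, refs["A"], ref_id="A")
        assert len(calls) == 1
        assert calls[0].kind == "DEL" and len(calls[0].ref_allele) == 1
        # left-normalisation may shift within a repeat, never far
        assert abs(calls[0].position - 11344) <= 3

    def test_sv_scale_gaps_excluded(self, refs):
        cons = sg.apply_allele(refs["B"], [AlleleEdit("DEL", 1501, 6851)])
        assert consensus_indels(cons, refs["B"]) == []


class TestPanelRecovery:
    def test_planted_sites_recovered_with_correct_genotypes(self, refs):
        """>= 98% of the planted catalog sites come back with the right
        alleles and zygosity on a noisy panel (scaled: 2 seeds at 100x)."""
        planted = planted_a1_sites()
        em = ErrorModel(**AMPLICON_ONLY)
        gts = [cat.vrn_a1_genotype(g)
               for g in ("GT1", "GT2", "GT3", "GT4", "GT5", "GT6")]
        for seed in (31, 32):
            reads, _ = sg.simulate_panel(gts, {"A": refs["A"]}, 100, em,
                                         sg.make_barcodes(8), seed,
                                         full_length_prob=0.9)
            by_cv = {}
            for r in reads:
                by_cv.setdefault(r.cultivar, []).append(r)
            found = set()
            ok_sites = 0
            for cv, rs in by_cv.items():
                alns = align_and_assign(rs, {"A": refs["A"]})
                pile = build_pileup(alns, refs["A"], ref_id="A")
                snps = [c for c in homopolymer_filter(
                    call_variants(pile, alignments=alns), refs["A"])
                    if c.filter == "pass"]
                cons, _ = reference_guided_consensus(alns, refs["A"])
                inds = [c for c in homopolymer_filter(
                    consensus_indels(cons, refs["A"], ref_id="A"),
                    refs["A"]) if c.filter == "pass"]
                snps = [c for c in indel_shadow_filter(snps, inds)
                        if c.filter == "pass"]
                found |= variant_positions(snps) | variant_positions(inds)
                # genotype check per cultivar at substitution sites
                row = cat.VRN_A1_GROUP_ALLELES[cv]
                ref_row = cat.VRN_A1_GROUP_ALLELES["GT3"]
                call_at = {c.position: c for c in snps}
                for i, pos in enumerate(cat.VRN_A1_POSITIONS):
                    a, r0 = row[i], ref_row[i]
                    if a == r0 or "-" in (a, r0) or len(a) > 1:
                        continue
                    want = {a} if a in "ACGT" else None
                    if want is None:  # IUPAC het
                        want = set({"Y": "CT", "S": "CG", "R": "AG"}[a])
                    c = call_at.get(pos)
                    if c is not None and (set(c.alleles) == want or
                                          (len(want) == 1 and
                                           c.zygosity == "hom" and
                                           set(c.alleles) <= want)):
                        ok_sites += 1
            n_sub_sites = sum(
                1 for cv in by_cv
                for i, pos in enumerate(cat.VRN_A1_POSITIONS)
                if cat.VRN_A1_GROUP_ALLELES[cv][i] !=
                cat.VRN_A1_GROUP_ALLELES["GT3"][i]
                and "-" not in (cat.VRN_A1_GROUP_ALLELES[cv][i],
                                cat.VRN_A1_GROUP_ALLELES["GT3"][i]))
            assert ok_sites / n_sub_sites >= 0.98
            assert len(found & set(planted)) >= 0.98 * len(planted)
            assert len(found - set(planted)) <= 1
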