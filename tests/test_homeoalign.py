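"""Homoeolog alignment, assignment, coverage and consensus."""

import numpy as np
import pytest

from homeoplex import catalog as cat
from homeoplex import synthgen as sg
from homeoplex.homeoalign import (AlignParams, LowCoverageError,
                                  align_and_assign, align_to_references,
                                  assign_homoeolog, coverage_stats,
                                  reference_guided_consensus)
from homeoplex.synthgen import ErrorModel

from helpers import AMPLICON_ONLY


def _subseq(refs, hom, start, ln):
    return refs[hom].sequence[start:start + ln]


class TestAlignment:
    def test_error_free_read_has_identity_one(self, refs):
        read = ("r", _subseq(refs, "A", 2000, 5000))
        cand = align_to_references(read, refs)
        assert cand["A"].identity == pytest.approx(1.0)
        assert cand["A"].ref_start == 2000 and cand["A"].ref_end == 7000

    def test_cross_homoeolog_identity_matches_divergence(self, refs):
        """A clean B read scored against A shows ~92% identity."""
        read = ("r", refs["B"].sequence)
        cand = align_to_references(read, refs)
        assert abs(cand["A"].identity - 0.92) < 0.025

    def test_reverse_strand_recovered(self, refs):
        read = ("r", sg.reverse_complement(_subseq(refs, "D", 100, 4000)))
        a = assign_homoeolog(align_to_references(read, refs))
        assert a.ref_id == "D" and a.strand == "-" and a.assignment == "unique"

    def test_planted_deletion_stays_single_operation(self, refs):
        tmpl = sg.apply_allele(refs["B"], [sg.AlleleEdit("DEL", 1501, 6851)])
        cand = align_to_references(("r", tmpl), refs)
        dels = [n for op, n in cand["B"].cigar if op == "D"]
        assert dels == [6851]

    def test_low_identity_is_unaligned(self, refs):
        rng = np.random.default_rng(0)
        seq = list(_subseq(refs, "A", 3000, 4000))
        for i in rng.choice(len(seq), size=int(0.25 * len(seq)),
                            replace=False):
            seq[i] = "ACGT"[(("ACGT".index(seq[i])) + 1) % 4]
        a = assign_homoeolog(align_to_references(("r", "".join(seq)), refs))
        assert a.identity < 0.80
        assert a.assignment == "unaligned"

    def test_equal_scores_are_ambiguous(self, refs):
        seq = _subseq(refs, "A", 2000, 3000)
        cand = align_to_references(("r", seq), {"X": seq, "Y": seq})
        a = assign_homoeolog(cand)
        assert a.assignment == "ambiguous"

    def test_assignment_accuracy_on_noisy_panel(self, refs):
        """>= 99% of default-error full-length reads map to their own
        homoeolog uniquely at ~8% divergence."""
        gts = [cat.sv_genotype("cv", [])]
        em = ErrorModel(**AMPLICON_ONLY)
        reads, truth = sg.simulate_panel(gts, refs, 35, em,
                                         sg.make_barcodes(4), seed=8,
                                         full_length_prob=1.0)
        alns = align_and_assign(reads, refs)
        correct = [a.ref_id == r.homoeolog and a.assignment == "unique"
                   for a, r in zip(alns, reads)]
        assert len(correct) >= 90
        assert np.mean(correct) >= 0.99


class TestCoverage:
    def test_uniform_panel_has_balanced_ratios(self, refs):
        em = ErrorModel.error_free(**AMPLICON_ONLY)
        gts = [cat.sv_genotype(f"cv{i}", []) for i in range(3)]
        reads, _ = sg.simulate_panel(gts, refs, 15, em, sg.make_barcodes(4),
                                     seed=2, full_length_prob=1.0)
        sample_of = {}
        for r in reads:
            sample_of[r.read_id] = r.cultivar
        alns = align_and_assign(reads, refs, sample_ids=sample_of)
        rep = coverage_stats(alns, {h: len(refs[h].sequence) for h in refs})
        ratios = rep.ratios["A/B"].dropna()
        assert ((ratios > 0.4) & (ratios < 2.5)).all()

    def test_cv_equals_direct_recomputation(self, refs):
        em = ErrorModel.error_free(**AMPLICON_ONLY)
        gts = [cat.sv_genotype(f"cv{i}", []) for i in range(4)]
        reads, _ = sg.simulate_panel(gts, refs, 12, em, sg.make_barcodes(4),
                                     seed=5, full_length_prob=0.9)
        sample_of = {r.read_id: r.cultivar for r in reads}
        alns = align_and_assign(reads, refs, sample_ids=sample_of)
        rep = coverage_stats(alns, {h: len(refs[h].sequence) for h in refs})
        col = rep.depth["A"]
        assert rep.cv["A"] == pytest.approx(col.std(ddof=1) / col.mean())

    def test_preferential_amplification_skews_ratio(self, refs):
        """A short deletion-carrying B amplicon with a strong amplification
        weight dominates coverage (ratio > 50), with A flagged low."""
        del_b = sg.TemplateCopy(edits=(sg.AlleleEdit("DEL", 1501, 6851),),
                                weight=100.0)
        gt = sg.CultivarGenotype("hb", {
            "A": [sg.TemplateCopy(weight=0.5)],
            "B": [del_b],
            "D": [sg.TemplateCopy(weight=1.0)]})
        em = ErrorModel.error_free(**AMPLICON_ONLY)
        reads, _ = sg.simulate_panel([gt], refs, 8, em, sg.make_barcodes(4),
                                     seed=3, full_length_prob=1.0)
        sample_of = {r.read_id: "hb" for r in reads}
        alns = align_and_assign(reads, refs, sample_ids=sample_of)
        rep = coverage_stats(alns, {h: len(refs[h].sequence) for h in refs},
                             low_coverage_threshold=11.0)
        assert rep.ratios.loc["hb", "A/B"] < 1 / 50
        assert ("hb", "A") in rep.low_coverage


class TestConsensus:
    def test_error_free_consensus_equals_template(self, refs):
        tmpl = _subseq(refs, "D", 0, 13000)
        reads = [("r%d" % i, tmpl) for i in range(5)]
        alns = [assign_homoeolog(align_to_references(r, {"D": refs["D"]}))
                for r in reads]
        cons, depth = reference_guided_consensus(alns, refs["D"])
        assert cons[:13000] == tmpl
        assert depth[:13000].min() == 5

    def test_planted_deletion_propagates(self, refs):
        tmpl = sg.apply_allele(refs["D"], [sg.AlleleEdit("DEL", 3000, 17)])
        alns = [assign_homoeolog(align_to_references((f"r{i}", tmpl),
                                                     {"D": refs["D"]}))
                for i in range(6)]
        cons, _ = reference_guided_consensus(alns, refs["D"])
        assert len(cons) == len(refs["D"].sequence) - 17

    def test_insufficient_reads_raise(self, refs):
        alns = [assign_homoeolog(align_to_references(
            ("r", refs["A"].sequence), {"A": refs["A"]}))]
        with pytest.raises(LowCoverageError):
            reference_guided_consensus(alns, refs["A"], min_reads=3)

    def test_identity_non_decreasing_in_coverage(self, refs):
        """Consensus accuracy improves (weakly) from 10x to 30x to 100x,
        checked across seeds on a 2 kb template."""
        tmpl = _subseq(refs, "A", 4000, 2000)
        em = ErrorModel(**AMPLICON_ONLY)
        gt = sg.CultivarGenotype("cv", {"A": [sg.TemplateCopy()]})
        wins = 0
        for seed in range(20):
            idents = []
            for cov in (10, 30, 100):
                reads, _ = sg.simulate_panel([gt], {"A": tmpl}, cov, em,
                                             sg.make_barcodes(4),
                                             seed=700 + seed,
                                             full_length_prob=1.0,
                                             min_read_len=300)
                alns = align_and_assign(reads, {"A": tmpl})
                cons, _ = reference_guided_consensus(alns, tmpl)
                idents.append(sg.pairwise_identity(cons, tmpl))
            if idents[0] <= idents[1] + 1e-9 and idents[1] <= idents[2] + 1e-9:
                wins += 1
            assert idents[2] >= 0.992
        assert wins >= 17  # monotone in nearly all seeds
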