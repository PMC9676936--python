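"""Synthetic-data generator: references, allele editing, reads, phenotypes."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from homeoplex import catalog as cat
from homeoplex import synthgen as sg
from homeoplex.synthgen import AlleleEdit, ErrorModel

from helpers import AMPLICON_ONLY, levenshtein


class TestReferences:
    def test_pairwise_identity_near_target(self, refs):
        seqs = [refs[h].sequence for h in "ABD"]
        for i in range(3):
            for j in range(i + 1, 3):
                ident = sg.pairwise_identity(seqs[i], seqs[j])
                assert abs(ident - 0.92) <= 0.02

    def test_identity_matches_quadratic_oracle(self, refs):
        """Generator-reported identity equals an independent O(n^2) aligner."""
        a, b = refs["A"].sequence, refs["B"].sequence
        d = levenshtein(a, b)
        oracle = 1.0 - d / max(len(a), len(b))
        assert abs(sg.pairwise_identity(a, b) - oracle) <= 0.005

    def test_full_identity_gives_identical_sequences(self):
        r = sg.generate_references(3, target_identity=1.0)
        assert r[0].sequence == r[1].sequence == r[2].sequence

    def test_deterministic_under_seed(self):
        a = sg.generate_references(5)
        b = sg.generate_references(5)
        assert all(x.sequence == y.sequence for x, y in zip(a, b))

    def test_feature_map_tiles_without_overlap(self, refs):
        for ref in refs.values():
            spans = sorted(ref.feature_map.values())
            assert spans[0][0] == 1 and spans[-1][1] == len(ref.sequence)
            for (_, e0), (s1, _) in zip(spans, spans[1:]):
                assert s1 == e0 + 1
            i1 = ref.feature_map["intron1"]
            # the first intron accounts for ~70% of the amplified target
            assert (i1[1] - i1[0] + 1) / len(ref.sequence) > 0.6

    def test_rejects_invalid_parameters(self):
        with pytest.raises(ValueError):
            sg.generate_references(1, target_identity=0.4)
        with pytest.raises(ValueError):
            sg.generate_references(1, gene_len=5_000)


class TestApplyAllele:
    def test_duplication_adds_exact_tandem_copy(self, refs):
        e = AlleleEdit("DUP", 8650, 838)
        out = sg.apply_allele(refs["B"], [e])
        assert len(out) == len(refs["B"].sequence) + 838
        assert out[8649:9487] == out[9487:10325]  # tandem copy

    def test_empty_edit_list_is_identity(self, refs):
        assert sg.apply_allele(refs["A"], []) == refs["A"].sequence

    def test_large_deletion_realigns_as_single_gap(self, refs):
        """Edited-vs-unedited alignment shows one 6,851-base deletion."""
        import edlib
        out = sg.apply_allele(refs["B"], [AlleleEdit("DEL", 1501, 6851)])
        res = edlib.align(out, refs["B"].sequence, mode="NW", task="path")
        assert res["editDistance"] == 6851

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.lists(st.tuples(st.integers(0, 180), st.sampled_from("SID"),
                              st.integers(1, 9)), max_size=6))
    def test_length_bookkeeping(self, raw):
        """Output length changes by the sum of signed edit lengths."""
        base = "ACGTTGCA" * 40
        edits, cursor = [], 1
        for gap, kind, ln in sorted(raw):
            pos = cursor + gap
            if kind == "S":
                alt = "A" if base[(pos - 1) % len(base)] != "A" else "C"
                e = AlleleEdit("SNP", pos, 1, alt)
            elif kind == "I":
                e = AlleleEdit("INS", pos, ln, "ACGTACGTA"[:ln])
            else:
                e = AlleleEdit("DEL", pos, ln)
            if e.span()[1] > len(base):
                continue
            edits.append(e)
            cursor = e.span()[1] + 1
        out = sg.apply_allele(base, edits)
        assert len(out) - len(base) == sum(e.signed_length for e in edits)

    def test_rejects_overlap_and_bad_snp(self):
        base = "ACGT" * 100
        with pytest.raises(ValueError):
            sg.apply_allele(base, [AlleleEdit("DEL", 10, 20),
                                   AlleleEdit("SNP", 15, 1, "A")])
        with pytest.raises(ValueError):
            sg.apply_allele("AAAA" + base, [AlleleEdit("SNP", 1, 1, "A")])
        with pytest.raises(ValueError):
            sg.apply_allele(base, [AlleleEdit("DEL", 399, 30)])


class TestSimulatePanel:
    def test_zero_rate_reads_are_exact_substrings(self, refs):
        gt = cat.sv_genotype("cv", [])
        em = ErrorModel.error_free(**AMPLICON_ONLY)
        reads, truth = sg.simulate_panel([gt], refs, 5, em,
                                         sg.make_barcodes(4), seed=4)
        templates = {h: refs[h].sequence for h in refs}
        assert len(reads) > 0
        for r in reads:
            assert not r.chimera
            assert r.sequence in templates[r.homoeolog]

    def test_configured_rates_recovered(self, refs):
        """Chimera and barcode-loss fractions land within a point of the
        configured probabilities at n ~ 10,000 reads."""
        em = ErrorModel(chimera_prob=0.152, barcode_loss_prob=0.30)
        gts = [cat.sv_genotype(f"cv{i}", []) for i in range(8)]
        reads, truth = sg.simulate_panel(gts, refs, 10_000 / 24, em,
                                         sg.make_barcodes(8), seed=2,
                                         full_length_prob=0.8)
        assert len(truth) > 8_000
        assert abs(truth.chimera.mean() - 0.152) <= 0.01
        assert abs((~truth.barcode_present).mean() - 0.30) <= 0.01
        # read-length histogram support
        longest = truth.template_len.max()
        assert truth.read_len.min() >= 400  # errors can shorten slightly
        assert truth.read_len.max() <= 1.1 * longest

    def test_dosage_follows_amplification_weights(self, refs):
        """2 x T + 1 x C templates at equal weight give a ~2/3 T fraction."""
        pos = 5000
        ref_base = refs["A"].sequence[pos - 1]
        alt = "T" if ref_base != "T" else "C"
        edit = AlleleEdit("SNP", pos, 1, alt)
        copies = [sg.TemplateCopy(edits=(edit,), weight=1 / 3),
                  sg.TemplateCopy(edits=(edit,), weight=1 / 3),
                  sg.TemplateCopy(edits=(), weight=1 / 3)]
        gt = sg.CultivarGenotype("cv", {"A": copies})
        em = ErrorModel.error_free(**AMPLICON_ONLY)
        reads, truth = sg.simulate_panel([gt], {"A": refs["A"]}, 600, em,
                                         sg.make_barcodes(4), seed=9)
        frac = (truth.copy_index < 2).mean()
        n = len(truth)
        assert abs(frac - 2 / 3) <= 3 * np.sqrt((2 / 9) / n)

    def test_byte_identical_outputs_under_seed(self, refs, tmp_path):
        gt = cat.sv_genotype("cv", ["Vrn-B1f"])
        em = ErrorModel(chimera_prob=0.1)
        out = []
        for k in range(2):
            reads, truth = sg.simulate_panel([gt], refs, 10, em,
                                             sg.make_barcodes(4), seed=11)
            fq = tmp_path / f"r{k}.fastq"
            sg.write_fastq(reads, fq)
            tv = tmp_path / f"t{k}.tsv"
            sg.write_truth(truth, tv)
            out.append((fq.read_bytes(), tv.read_bytes()))
        assert out[0] == out[1]

    def test_rejects_degenerate_inputs(self, refs):
        gt = cat.sv_genotype("cv", [])
        em = ErrorModel()
        with pytest.raises(ValueError):
            sg.simulate_panel([], refs, 10, em, sg.make_barcodes(4), 1)
        with pytest.raises(ValueError):
            sg.simulate_panel([gt], refs, 0, em, sg.make_barcodes(4), 1)
        with pytest.raises(ValueError):
            sg.simulate_panel([gt, gt], refs, 10, em, ["ACGT" * 6], 1)


class TestPhenotypes:
    def test_default_model_emits_twenty_traits(self):
        table = sg.simulate_phenotypes(["g1", "g2"], sg.PhenoModel(),
                                       n_per_group=5, seed=0)
        assert table.shape == (10, 21)  # group column + 20 traits
        assert len(sg.PhenoModel().trait_names) == 20

    def test_null_effects_give_equal_group_means(self):
        table = sg.simulate_phenotypes(["g1", "g2"], sg.PhenoModel(),
                                       n_per_group=200, seed=3)
        for trait, mean, sd in sg.DEFAULT_TRAITS:
            g = table.groupby("group")[trait].mean()
            se = sd * np.sqrt(2 / 200)
            assert abs(g["g1"] - g["g2"]) < 3 * se

    def test_planted_effect_shifts_mean(self):
        model = sg.PhenoModel(effects={"sv": {"grain_yield_dt_ha": -9.5}})
        table = sg.simulate_phenotypes(["sv", "intact"], model,
                                       n_per_group=300, seed=5)
        g = table.groupby("group")["grain_yield_dt_ha"].mean()
        assert g["sv"] < g["intact"] - 5

    def test_rejects_bad_model(self):
        with pytest.raises(ValueError):
            sg.PhenoModel(traits=(("t", 1.0, 0.0),))
        with pytest.raises(ValueError):
            sg.simulate_phenotypes([], sg.PhenoModel(), 5, 1)
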