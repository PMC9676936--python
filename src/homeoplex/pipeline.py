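"""End-to-end pipeline: simulate -> demux -> align -> call -> phase ->
classify -> scan -> associate, with one parameter block, per-stage outputs
in standard formats, and a provenance manifest.

Every stage is a pure function of its inputs, so re-running a stage (or the
whole pipeline with the same seed) reproduces its outputs byte for byte.
The manifest records the read-count funnel raw >= classified >= filtered >=
assigned, the analysis parameters and per-stage output files.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import catalog, synthgen
from .assoc import association_report
from .classify import genotype_groups, sequence_type
from .demux import FilterParams, demux_reads, trim_barcodes
from .g4scan import G4Params, find_g4, write_bed
from .homeoalign import (AlignParams, LowCoverageError, align_and_assign,
                         coverage_stats, reference_guided_consensus,
                         write_sam)
from .phasecn import allele_dosage, copy_number, dosage_cluster, \
    phase_haplotypes
from .snpcall import SnpParams, build_pileup, call_variants, \
    consensus_indels, homopolymer_filter, indel_shadow_filter, write_vcf
from .svcall import SVParams, call_svs, classify_insertion, merge_svs, \
    write_sv_vcf
from .synthgen import ErrorModel, PhenoModel, simulate_phenotypes

__all__ = ["PipelineParams", "run_pipeline"]


@dataclass
class PipelineParams:
    """All analysis thresholds in one validated block."""

    min_read_len: int = 2_000
    max_read_len: int = 16_000
    min_q: float = 8.0
    min_identity: float = 0.80
    min_aligned_fraction: float = 0.50
    uniqueness_margin: int = 50
    sv_min_len: int = 30
    sv_min_support: int = 10
    sv_merge_window: int = 500
    snp_min_count: int = 3
    snp_min_qual: float = 30.0
    snp_min_depth: int = 11
    homopolymer_run: int = 4
    consensus_min_reads: int = 3
    low_coverage_threshold: float = 11.0
    sequence_type_identity: float = 0.99
    alpha: float = 0.05
    hap_min_support: int = 10
    dosage_min_depth: int = 30

    def __post_init__(self) -> None:
        if not 0 < self.min_identity <= 1 or not 0 < self.min_aligned_fraction <= 1:
            raise ValueError("identity/aligned-fraction must be in (0,1]")
        if self.min_read_len >= self.max_read_len:
            raise ValueError("min_read_len must be < max_read_len")
        for name in ("sv_min_len", "sv_min_support", "snp_min_count",
                     "homopolymer_run", "consensus_min_reads",
                     "hap_min_support"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0,1)")

    def filter_params(self) -> FilterParams:
        return FilterParams(self.min_read_len, self.max_read_len, self.min_q)

    def align_params(self) -> AlignParams:
        return AlignParams(self.min_identity, self.min_aligned_fraction,
                           self.uniqueness_margin)

    def sv_params(self) -> SVParams:
        return SVParams(self.sv_min_len, self.sv_min_support,
                        merge_window=self.sv_merge_window)

    def snp_params(self) -> SnpParams:
        return SnpParams(self.snp_min_depth, self.snp_min_count,
                         min_qual=self.snp_min_qual,
                         homopolymer_run=self.homopolymer_run)


def _build_genotypes(config: Mapping) -> list[synthgen.CultivarGenotype]:
    scenario = config.get("scenario", "table4")
    if scenario == "table4":
        return catalog.table4_scenario()
    if isinstance(scenario, str):
        raise ValueError(f"unknown scenario {scenario!r}")
    out = []
    for spec in scenario:
        cid = spec["cultivar_id"]
        if "vrn_a1_group" in spec:
            out.append(catalog.vrn_a1_genotype(spec["vrn_a1_group"], cid))
        else:
            out.append(catalog.sv_genotype(cid, spec.get("sv_alleles", [])))
    return out


def run_pipeline(config: Mapping, out_dir, seed: int) -> dict:
    """Run every stage on a synthetic panel and return the manifest.

    ``config`` keys (all optional): ``scenario`` ("table4" or a list of
    cultivar specs), ``mean_coverage``, ``error_model`` (field overrides),
    ``target_identity``, ``gene_len``, ``full_length_prob``,
    ``params`` (PipelineParams overrides), ``phenotypes`` ({"effects": ...,
    "n_per_group": ...} to plant trait differences between the called
    groups).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = PipelineParams(**config.get("params", {}))
    rng = np.random.default_rng(seed)
    seeds = {k: int(rng.integers(2 ** 31)) for k in
             ("refs", "reads", "phenotypes")}
    manifest: dict = {"seed": seed, "params": asdict(params),
                      "config": {k: v for k, v in config.items()},
                      "stages": {}}

    # --- simulate ----------------------------------------------------------
    refs_raw = synthgen.generate_references(
        seeds["refs"], config.get("target_identity", 0.92),
        config.get("gene_len", 13_000))
    refs = catalog.prepare_panel(refs_raw)
    genotypes = _build_genotypes(config)
    em = ErrorModel(**config.get("error_model", {}))
    barcodes = synthgen.make_barcodes(max(len(genotypes), 4))
    reads, truth = synthgen.simulate_panel(
        genotypes, refs, config.get("mean_coverage", 100.0), em, barcodes,
        seeds["reads"], config.get("full_length_prob", 0.9))
    synthgen.write_fasta(refs.values(), out / "references.fasta")
    synthgen.write_fastq(reads, out / "reads.fastq")
    synthgen.write_truth(truth, out / "truth.tsv")
    manifest["stages"]["simulate"] = {"n_reads": len(reads),
                                      "n_cultivars": len(genotypes)}

    # --- demux -------------------------------------------------------------
    sample_names = [g.cultivar_id for g in genotypes]
    cls = demux_reads(reads, barcodes[:len(genotypes)], sample_names,
                      params.filter_params())
    pd.DataFrame([{"read_id": c.read_id, "status": c.status,
                   "sample_id": c.sample_id or "",
                   "filter_reason": c.filter_reason,
                   "mean_q": round(c.mean_q, 3)} for c in cls]).to_csv(
        out / "classification.tsv", sep="\t", index=False)
    n_raw = len(reads)
    n_classified = sum(c.status in ("assigned", "filtered") for c in cls)
    n_filtered = sum(c.status == "assigned" for c in cls)
    by_id = {r.read_id: r for r in reads}
    bc_of = dict(zip(sample_names, barcodes))
    passing = [(trim_barcodes(by_id[c.read_id], bc_of[c.sample_id],
                              params.filter_params()), c.sample_id)
               for c in cls if c.status == "assigned"]

    # --- align -------------------------------------------------------------
    sample_of = {r.read_id: s for r, s in passing}
    alignments = align_and_assign([r for r, _ in passing], refs,
                                  params.align_params(), sample_of)
    write_sam(alignments, refs, out / "alignments.sam")
    unique = [a for a in alignments if a.assignment == "unique"]
    n_assigned = len(unique)
    manifest["stages"]["demux_align"] = {
        "raw": n_raw, "classified": n_classified, "filtered": n_filtered,
        "assigned": n_assigned}

    cov = coverage_stats(unique, {h: len(r.sequence)
                                  for h, r in refs.items()},
                         params.low_coverage_threshold)
    cov.depth.round(3).to_csv(out / "coverage.tsv", sep="\t")
    manifest["stages"]["coverage"] = {
        "cv": {h: round(v, 4) if np.isfinite(v) else None
               for h, v in cov.cv.items()},
        "low_coverage": cov.low_coverage}

    # --- per sample+homoeolog calling -------------------------------------
    grouped: dict[tuple[str, str], list] = {}
    for a in unique:
        grouped.setdefault((a.sample_id, a.ref_id), []).append(a)

    consensus_fa = open(out / "consensus.fasta", "w")
    sv_calls = []
    small_by_sample: dict[str, list] = {s: [] for s in sample_names}
    pileups: dict[tuple[str, str], object] = {}
    seqtype_rows = []
    for (sample, hom), alns in sorted(grouped.items()):
        svs = [classify_insertion(c, refs[hom], params.sv_params())
               for c in call_svs(alns, params.sv_params(), sample)]
        sv_calls.extend(svs)
        pile = build_pileup(alns, refs[hom], ref_id=hom)
        pileups[(sample, hom)] = pile
        small = homopolymer_filter(
            call_variants(pile, params.snp_params(), alns), refs[hom],
            params.homopolymer_run)
        try:
            cons, _ = reference_guided_consensus(alns, refs[hom],
                                                 params.consensus_min_reads)
            consensus_fa.write(f">{sample}|{hom}\n{cons}\n")
            inds = homopolymer_filter(
                consensus_indels(cons, refs[hom], ref_id=hom), refs[hom],
                params.homopolymer_run)
            small = indel_shadow_filter(
                small, [c for c in inds if c.filter == "pass"])
            small_by_sample[sample].extend(inds)
            st = sequence_type(cons, {h: r for h, r in refs.items()},
                               sample, hom, params.sequence_type_identity)
            seqtype_rows.append({"sample": sample, "homoeolog": hom,
                                 "best_reference": st.best_reference,
                                 "identity": round(st.identity, 5),
                                 "status": st.status})
        except LowCoverageError:
            seqtype_rows.append({"sample": sample, "homoeolog": hom,
                                 "best_reference": "", "identity": np.nan,
                                 "status": "low_coverage"})
        small_by_sample[sample].extend(small)
    consensus_fa.close()

    merged = merge_svs(sv_calls, params.sv_merge_window)
    write_sv_vcf(merged, refs, out / "svs.vcf")
    pd.DataFrame([{"ref": c.ref_id, "position": c.position, "type": c.type,
                   "length": c.length, "support": c.support,
                   "carriers": ",".join(c.carriers)} for c in merged]
                 ).to_csv(out / "svs.tsv", sep="\t", index=False)
    write_vcf(small_by_sample, refs, out / "variants.vcf")
    pd.DataFrame(seqtype_rows).to_csv(out / "sequence_types.tsv", sep="\t",
                                      index=False)
    manifest["stages"]["calling"] = {
        "n_sv_records": len(merged),
        "n_small_variant_sites": len({(c.ref_id, c.position, c.kind)
                                      for cs in small_by_sample.values()
                                      for c in cs if c.filter == "pass"})}

    # --- phase + copy number (homoeolog A) ---------------------------------
    cn_rows = []
    excluded = set(catalog.VRN_A1_HET_EXCLUDED_FROM_PHASING)
    for sample in sample_names:
        calls = [c for c in small_by_sample[sample]
                 if c.ref_id == "A" and c.filter == "pass"]
        het_sites = [c.position for c in calls
                     if c.zygosity == "het" and c.kind == "SNP"
                     and c.position not in excluded]
        pile = pileups.get((sample, "A"))
        if pile is None:
            continue
        dosage_site = config.get("dosage_site", catalog.VRN_A1_DOSAGE_SITE)
        het_at_dosage = any(c.position == dosage_site and c.zygosity == "het"
                            for c in calls)
        if not het_sites:
            est = copy_number(
                phase_haplotypes(grouped.get((sample, "A"), []),
                                 [dosage_site], params.hap_min_support),
                "unavailable", "hom")
        else:
            site_alleles = {c.position: set(c.alleles) for c in calls
                            if c.position in het_sites}
            hs = phase_haplotypes(grouped[(sample, "A")], het_sites,
                                  params.hap_min_support, site_alleles,
                                  realign_ref=refs["A"].sequence)
            if het_at_dosage:
                dos = allele_dosage(pile, dosage_site,
                                    min_depth=params.dosage_min_depth,
                                    alignments=grouped[(sample, "A")])
                est = copy_number(hs, dosage_cluster(dos), "het")
                est.dosage = dos
            else:
                est = copy_number(hs, "unavailable", "hom")
        cn_rows.append({"sample": sample, "n_haplotypes": est.n_haplotypes,
                        "cluster": est.cluster,
                        "copy_number": est.copy_number,
                        "evidence": est.evidence})
    pd.DataFrame(cn_rows).to_csv(out / "copy_number.tsv", sep="\t",
                                 index=False)
    manifest["stages"]["copy_number"] = {
        r["sample"]: r["copy_number"] for r in cn_rows}

    # --- grouping ----------------------------------------------------------
    all_sites = sorted({(c.ref_id, c.position) for cs in
                        small_by_sample.values() for c in cs
                        if c.filter == "pass"})
    matrix = {}
    for sample in sample_names:
        calls = {(c.ref_id, c.position): c for c in small_by_sample[sample]
                 if c.filter == "pass"}
        row = []
        for key in all_sites:
            c = calls.get(key)
            if c is None:
                row.append("ref")
            else:
                row.append("/".join(sorted(c.alleles)))
        matrix[sample] = row
    mdf = pd.DataFrame.from_dict(matrix, orient="index",
                                 columns=[f"{r}:{p}" for r, p in all_sites])
    assignments, n_groups = genotype_groups(mdf) if not mdf.empty else ([], 0)
    groups = {a.sample_id: a.group for a in assignments} or \
        {s: "G1" for s in sample_names}
    pd.DataFrame([{"sample": s, "group": g} for s, g in groups.items()]
                 ).to_csv(out / "groups.tsv", sep="\t", index=False)
    mdf.to_csv(out / "variant_matrix.tsv", sep="\t")
    manifest["stages"]["grouping"] = {"n_groups": n_groups or 1}

    # --- G4 scan -----------------------------------------------------------
    g4_rows = []
    for hom, ref in sorted(refs.items()):
        motifs = find_g4(ref.sequence, G4Params())
        write_bed(motifs, out / f"g4_{hom}.bed", name=hom)
        g4_rows.append({"sequence": hom, "n_motifs": len(motifs)})
    pd.DataFrame(g4_rows).to_csv(out / "g4_summary.tsv", sep="\t",
                                 index=False)
    manifest["stages"]["g4"] = {r["sequence"]: r["n_motifs"]
                                for r in g4_rows}

    # --- association -------------------------------------------------------
    pheno_cfg = config.get("phenotypes")
    if pheno_cfg:
        model = PhenoModel(effects=pheno_cfg.get("effects", {}))
        n_per = int(pheno_cfg.get("n_per_group", 20))
        labels = sorted(set(groups.values()))
        table = simulate_phenotypes(labels, model, n_per,
                                    seeds["phenotypes"])
        table.to_csv(out / "phenotypes.tsv", sep="\t")
        report = association_report(table, ["group"], params.alpha)
        report.to_csv(out / "associations.tsv", sep="\t", index=False)
        manifest["stages"]["association"] = {
            "n_tests": int(len(report)),
            "n_significant": int(report["significant"].sum())
            if not report.empty else 0}

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=str)
    return manifest
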