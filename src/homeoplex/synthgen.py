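"""Synthetic data generation for homoeolog-resolved amplicon analysis.

This module builds everything a truth-aware end-to-end run needs:

* three homoeologous reference amplicons (A/B/D-like) derived from a common
  ancestor at a controlled pairwise identity (~92% by default, the divergence
  level typical of wheat subgenome homoeologs),
* allele editing (SNP / INS / DEL / DUP) on those references,
* barcoded ONT-like reads with a configurable error model (substitutions,
  indels with homopolymer bias, chimeric molecules, barcode loss, per-base
  qualities and amplification bias), together with a per-read truth table,
* a multi-trait phenotype table with planted group effects.

Coordinate convention
---------------------
All planted positions are 1-based and counted from the first base of the
amplicon, i.e. from the base immediately following the 3' end of the forward
primer.  Internal arithmetic is 0-based half-open; conversion happens only at
the interfaces of this module.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np
import pandas as pd

__all__ = [
    "HomoeologReference",
    "AlleleEdit",
    "TemplateCopy",
    "CultivarGenotype",
    "ErrorModel",
    "PhenoModel",
    "SimRead",
    "generate_references",
    "apply_allele",
    "make_barcodes",
    "simulate_panel",
    "simulate_phenotypes",
    "pairwise_identity",
    "reverse_complement",
    "write_fastq",
    "write_fasta",
    "DEFAULT_TRAITS",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = {c: i for i, c in enumerate("ACGT")}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

# Exon/intron block sizes downstream of the first intron.  The first intron
# absorbs whatever length is left, which makes it ~70% of a default 13 kb gene
# — the architecture of VRN1, whose large first intron carries most of the
# known regulatory variation.
_EXON1_LEN = 200
_DOWNSTREAM_BLOCKS = [
    ("exon2", 50), ("intron2", 100), ("exon3", 30), ("intron3", 20),
    ("exon4", 60), ("intron4", 100), ("exon5", 30), ("intron5", 40),
    ("exon6", 12), ("intron6", 337), ("exon7", 121), ("intron7", 400),
    ("exon8", 1500),
]
_DOWNSTREAM_LEN = sum(n for _, n in _DOWNSTREAM_BLOCKS)

# Quadruplex-forming G-rich motif planted in every reference so that motif
# scanning always has a known positive in the promoter and in intron 1.
G4_MOTIF = "GGGCTAGGGCTAGGGCTAGGG"
# Motif start positions (1-based): one in the promoter, two in intron 1.
G4_PLANT_POSITIONS = (372, 5800, 9000)


def reverse_complement(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def _to_codes(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    out = np.empty(arr.size, dtype=np.uint8)
    for i, c in enumerate(b"ACGT"):
        out[arr == c] = i
    return out


def _to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode()


@dataclass
class HomoeologReference:
    """One homoeologous reference amplicon.

    ``feature_map`` holds named 1-based inclusive intervals (promoter,
    exons 1-8, introns 1-7) that tile the sequence without overlap.
    """

    id: str
    sequence: str
    promoter_len: int = 700
    feature_map: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.sequence) - set("ACGT"):
            raise ValueError("reference alphabet must be {A,C,G,T}")
        if len(self.sequence) < self.promoter_len + 10_000:
            raise ValueError("reference shorter than promoter + 10 kb gene body")
        if self.feature_map:
            spans = sorted(self.feature_map.values())
            if spans[0][0] != 1 or spans[-1][1] != len(self.sequence):
                raise ValueError("feature map does not tile the sequence")
            for (_, e0), (s1, _) in zip(spans, spans[1:]):
                if s1 != e0 + 1:
                    raise ValueError("feature intervals overlap or leave gaps")

    def feature_of(self, position: int) -> str:
        """Name of the feature containing a 1-based position."""
        for name, (s, e) in self.feature_map.items():
            if s <= position <= e:
                return name
        raise ValueError(f"position {position} outside reference")


@dataclass(frozen=True)
class AlleleEdit:
    """A planted edit, positioned on the unedited reference.

    ``position`` is the first affected base (1-based): a SNP replaces it, a
    DEL removes ``length`` bases starting there, an INS places ``alt`` so that
    its first base lands at ``position`` (the former occupant shifts right),
    and a DUP inserts a tandem copy of the ``length`` reference bases starting
    at ``position`` immediately after them.
    """

    kind: str  # SNP | INS | DEL | DUP
    position: int
    length: int = 1
    alt: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("SNP", "INS", "DEL", "DUP"):
            raise ValueError(f"unknown edit kind {self.kind!r}")
        if self.position < 1:
            raise ValueError("position must be >= 1")
        if self.length < 1:
            raise ValueError("length must be >= 1")
        if self.kind == "SNP" and (len(self.alt) != 1 or self.alt not in "ACGT"):
            raise ValueError("SNP needs a single-base alt")
        if self.kind == "INS" and len(self.alt) != self.length:
            raise ValueError("INS alt length must equal `length`")
        if self.kind in ("DEL", "DUP") and self.alt:
            raise ValueError(f"{self.kind} takes no alt sequence")

    @property
    def signed_length(self) -> int:
        """Length change this edit causes on the sequence."""
        if self.kind == "SNP":
            return 0
        if self.kind == "DEL":
            return -self.length
        return self.length  # INS, DUP

    def span(self) -> tuple[int, int]:
        """1-based inclusive interval of reference bases this edit touches."""
        if self.kind == "INS":
            return (self.position, self.position)
        return (self.position, self.position + self.length - 1)


@dataclass
class TemplateCopy:
    """One physical gene copy of a homoeolog in a cultivar."""

    edits: tuple[AlleleEdit, ...] = ()
    haplotype: str = "hap"
    weight: float = 1.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.weight) or self.weight < 0:
            raise ValueError("amplification weight must be finite and >= 0")


@dataclass
class CultivarGenotype:
    """Per-homoeolog template copies for one cultivar."""

    cultivar_id: str
    copies: dict[str, list[TemplateCopy]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for hom, copies in self.copies.items():
            if len(copies) == 0:
                raise ValueError(
                    f"{self.cultivar_id}/{hom}: at least one template copy "
                    "required (drop the homoeolog key for a null allele)"
                )


@dataclass
class ErrorModel:
    """Per-base ONT-like error process.

    Defaults approximate R9.4.1-era accuracy: substitutions 3%, insertions
    2%, deletions 4%, with indel rates tripled inside homopolymer runs of
    four or more.  A zero-rate model reproduces template substrings exactly.
    """

    sub_rate: float = 0.03
    ins_rate: float = 0.02
    del_rate: float = 0.04
    homopolymer_mult: float = 3.0
    homopolymer_min_run: int = 4
    chimera_prob: float = 0.0
    barcode_loss_prob: float = 0.0
    read_q_sd: float = 2.5  # between-read spread of the emitted quality
    base_q_sd: float = 1.5  # within-read per-base quality noise

    def __post_init__(self) -> None:
        for name in ("sub_rate", "ins_rate", "del_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 0.2:
                raise ValueError(f"{name} must be in [0, 0.2]")
        if self.homopolymer_mult < 1:
            raise ValueError("homopolymer multiplier must be >= 1")
        for name in ("chimera_prob", "barcode_loss_prob"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")

    @classmethod
    def error_free(cls, **kw) -> "ErrorModel":
        return cls(sub_rate=0.0, ins_rate=0.0, del_rate=0.0, **kw)


@dataclass
class SimRead:
    """A simulated read plus its ground-truth labels."""

    read_id: str
    sequence: str
    qualities: np.ndarray  # Phred ints
    cultivar: str
    homoeolog: str
    copy_index: int
    chimera: bool
    barcode_present: bool
    template_len: int


# ---------------------------------------------------------------------------
# reference generation
# ---------------------------------------------------------------------------

def _feature_map(gene_len: int, promoter_len: int) -> dict[str, tuple[int, int]]:
    intron1 = gene_len - _EXON1_LEN - _DOWNSTREAM_LEN
    if intron1 < 1000:
        raise ValueError("gene too short for the fixed exon/intron layout")
    fm = {"promoter": (1, promoter_len)}
    pos = promoter_len + 1
    for name, n in [("exon1", _EXON1_LEN), ("intron1", intron1)] + _DOWNSTREAM_BLOCKS:
        fm[name] = (pos, pos + n - 1)
        pos += n
    return fm


def _homopolymer_mask(codes: np.ndarray, min_run: int) -> np.ndarray:
    """Boolean mask of bases inside single-base runs of length >= min_run."""
    n = codes.size
    if n == 0:
        return np.zeros(0, dtype=bool)
    change = np.empty(n, dtype=bool)
    change[0] = True
    change[1:] = codes[1:] != codes[:-1]
    run_id = np.cumsum(change) - 1
    run_len = np.bincount(run_id)
    return run_len[run_id] >= min_run


def _diverge(anc: np.ndarray, rate: float, rng: np.random.Generator,
             protected: np.ndarray) -> np.ndarray:
    """Mutate an ancestor: 90% substitutions, 10% indels of 1-5 bp."""
    n = anc.size
    n_events = int(round(rate * n))
    seq = anc.copy()
    positions = rng.choice(np.flatnonzero(~protected), size=n_events, replace=False)
    kinds = rng.random(n_events)
    sub_pos = positions[kinds < 0.9]
    seq[sub_pos] = (seq[sub_pos] + rng.integers(1, 4, sub_pos.size)) % 4
    indel_pos = np.sort(positions[kinds >= 0.9])[::-1]
    out = list(seq)
    for p in indel_pos:
        ln = int(rng.integers(1, 6))
        if rng.random() < 0.5:  # deletion; never reaches into protected spans
            stop = min(p + ln, n)
            if protected[p:stop].any():
                stop = p + int(np.argmax(protected[p:stop]))
            del out[p:stop]
        else:
            out[p:p] = list(rng.integers(0, 4, ln, dtype=np.uint8))
    return np.array(out, dtype=np.uint8)


def pairwise_identity(a: str, b: str) -> float:
    """Global-alignment identity, defined as 1 - editdist / max(len a, len b)."""
    d = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
    return 1.0 - d / max(len(a), len(b))


def generate_references(seed: int, target_identity: float = 0.92,
                        gene_len: int = 13_000, promoter_len: int = 700,
                        ) -> tuple[HomoeologReference, HomoeologReference, HomoeologReference]:
    """Generate three homoeolog references at a controlled pairwise identity.

    A random ancestor of ``promoter_len + gene_len`` bases is mutated into
    three independent lineages; the per-lineage mutation rate is calibrated
    (a couple of deterministic iterations) so that all three pairwise
    global-alignment identities land within +/-0.02 of ``target_identity``.
    Each reference keeps the planted G-rich quadruplex motifs (one in the
    promoter, two in intron 1) intact.  Deterministic under ``seed``.
    """
    if not 0.5 < target_identity <= 1.0:
        raise ValueError("target_identity must be in (0.5, 1.0]")
    if gene_len < 10_000:
        raise ValueError("gene_len must be >= 10,000")
    total = promoter_len + gene_len
    rng = np.random.default_rng(seed)
    anc = rng.integers(0, 4, total, dtype=np.uint8)

    motif = _to_codes(G4_MOTIF)
    protected = np.zeros(total, dtype=bool)
    for pos in G4_PLANT_POSITIONS:
        anc[pos - 1:pos - 1 + motif.size] = motif
        protected[pos - 2:pos + motif.size] = True  # motif plus 1-base flanks

    if target_identity == 1.0:
        seqs = [anc, anc, anc]
    else:
        rate = (1.0 - target_identity) / 2.0
        seqs = None
        for attempt in range(6):
            child = [np.random.default_rng((seed, attempt, k)) for k in range(3)]
            cand = [_diverge(anc, rate, child[k], protected) for k in range(3)]
            idents = [pairwise_identity(_to_str(cand[i]), _to_str(j))
                      for i, j in ((0, cand[1]), (0, cand[2]), (1, cand[2]))]
            if all(abs(x - target_identity) <= 0.008 for x in idents):
                seqs = cand
                break
            mean_div = np.mean([1 - x for x in idents])
            if mean_div <= 0:
                raise ValueError("identity/length combination unattainable")
            rate *= (1.0 - target_identity) / mean_div
        if seqs is None:
            raise ValueError(
                f"could not reach pairwise identity {target_identity} +/- 0.02")
    # indel divergence shifts each lineage's length slightly; the first
    # intron absorbs the difference in that lineage's annotation
    return tuple(
        HomoeologReference(id=label, sequence=_to_str(s),
                           promoter_len=promoter_len,
                           feature_map=_feature_map(s.size - promoter_len,
                                                    promoter_len))
        for label, s in zip(("A", "B", "D"), seqs)
    )


# ---------------------------------------------------------------------------
# allele editing
# ---------------------------------------------------------------------------

def apply_allele(ref: "HomoeologReference | str", edits: Sequence[AlleleEdit]) -> str:
    """Apply non-overlapping edits (sorted by position) to a sequence.

    Edits are applied right-to-left so that earlier coordinates stay valid.
    The output length equals the input length plus the sum of signed edit
    lengths.
    """
    seq = ref.sequence if isinstance(ref, HomoeologReference) else ref
    if not edits:
        return seq
    positions = [e.position for e in edits]
    if positions != sorted(positions):
        raise ValueError("edits must be sorted by position")
    for a, b in zip(edits, edits[1:]):
        if a.span()[1] >= b.span()[0] and not (
                a.kind == "INS" and a.position == b.position):
            raise ValueError(f"overlapping edits at {a.position}/{b.position}")
    n = len(seq)
    out = seq
    for e in reversed(edits):
        p = e.position - 1
        if e.span()[1] > n:
            raise ValueError(f"edit at {e.position} out of range (len {n})")
        if e.kind == "SNP":
            if out[p] == e.alt:
                raise ValueError(f"SNP alt equals reference base at {e.position}")
            out = out[:p] + e.alt + out[p + 1:]
        elif e.kind == "DEL":
            out = out[:p] + out[p + e.length:]
        elif e.kind == "INS":
            out = out[:p] + e.alt + out[p:]
        else:  # DUP: tandem copy of ref[p : p+length] inserted after it
            seg = out[p:p + e.length]
            out = out[:p + e.length] + seg + out[p + e.length:]
    return out


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

def make_barcodes(n: int, length: int = 24, seed: int = 99) -> list[str]:
    """Deterministic set of random barcodes (PBC096-like, 24 bp)."""
    rng = np.random.default_rng(seed)
    out = []
    while len(out) < n:
        bc = _to_str(rng.integers(0, 4, length, dtype=np.uint8))
        # random 24-mers are pairwise distant with overwhelming probability;
        # reject the rare near-duplicate to keep demultiplexing well posed
        if all(edlib.align(bc, other, mode="NW", task="distance",
                           k=8)["editDistance"] == -1 for other in out):
            out.append(bc)
    return out


def _apply_errors(codes: np.ndarray, em: ErrorModel, rng: np.random.Generator,
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Apply the error process to template codes; return (read codes, quals)."""
    n = codes.size
    if em.sub_rate == em.ins_rate == em.del_rate == 0.0:
        q = np.full(n, 30, dtype=np.int16)
        return codes.copy(), q
    hp = _homopolymer_mask(codes, em.homopolymer_min_run)
    mult = np.where(hp, em.homopolymer_mult, 1.0)
    del_p = np.minimum(em.del_rate * mult, 0.9)
    ins_p = np.minimum(em.ins_rate * mult, 0.9)
    keep = rng.random(n) >= del_p
    out = codes.copy()
    sub_mask = keep & (rng.random(n) < em.sub_rate)
    out[sub_mask] = (out[sub_mask] + rng.integers(1, 4, int(sub_mask.sum()))) % 4
    ins_mask = keep & (rng.random(n) < ins_p)
    counts = keep.astype(np.int64) + ins_mask  # inserted base = stutter copy
    read = np.repeat(out, counts)
    # per-base quality from the local error rate (logistic-free closed form),
    # plus a per-read offset so that mean-Q filtering has something to do
    p_local = np.minimum(del_p + ins_p + em.sub_rate, 0.5)
    q_true = -10.0 * np.log10(p_local + 1e-3)
    q_read = np.repeat(q_true, counts)
    offset = rng.normal(0.0, em.read_q_sd)
    q = np.clip(np.rint(q_read + offset + rng.normal(0.0, em.base_q_sd,
                                                     q_read.size)), 2, 40)
    return read, q.astype(np.int16)


def simulate_panel(genotypes: Sequence[CultivarGenotype],
                   refs: Mapping[str, "HomoeologReference | str"],
                   mean_coverage: float,
                   error_model: ErrorModel,
                   barcode_set: Sequence[str],
                   seed: int,
                   full_length_prob: float = 0.8,
                   min_read_len: int = 500,
                   ) -> tuple[list[SimRead], pd.DataFrame]:
    """Simulate a barcoded amplicon panel with per-read ground truth.

    For every cultivar and homoeolog the expected read count is
    ``mean_coverage * sum(copy weights)`` (Poisson), and each read's template
    copy is drawn with probability proportional to its amplification weight.
    Reads are full-length with probability ``full_length_prob``, otherwise a
    truncated fragment keeping one molecule end.  With probability
    ``error_model.chimera_prob`` a read is the concatenation of two barcoded
    molecules (so a barcode ends up mid-read); with probability
    ``error_model.barcode_loss_prob`` the barcodes are absent.  Deterministic
    under ``seed``.
    """
    if not genotypes:
        raise ValueError("empty genotype list")
    if mean_coverage <= 0:
        raise ValueError("mean_coverage must be > 0")
    if len(barcode_set) < len(genotypes):
        raise ValueError("need at least one barcode per genotype")
    rng = np.random.default_rng(seed)
    ref_seqs = {h: (r.sequence if isinstance(r, HomoeologReference) else r)
                for h, r in refs.items()}

    # pre-compute template sequences
    templates: dict[tuple[int, str, int], np.ndarray] = {}
    for gi, g in enumerate(genotypes):
        for hom, copies in g.copies.items():
            if hom not in ref_seqs:
                raise KeyError(f"genotype {g.cultivar_id} references unknown "
                               f"homoeolog {hom!r}")
            for ci, cp in enumerate(copies):
                templates[(gi, hom, ci)] = _to_codes(
                    apply_allele(ref_seqs[hom], list(cp.edits)))

    # first pass: molecule specs (sample, homoeolog, copy, fragment, barcode?)
    specs: list[tuple[int, str, int, int, int, bool]] = []
    for gi, g in enumerate(genotypes):
        for hom, copies in g.copies.items():
            w = np.array([c.weight for c in copies], dtype=float)
            if w.sum() == 0:
                continue
            n_reads = rng.poisson(mean_coverage * w.sum())
            picks = rng.choice(len(copies), size=n_reads, p=w / w.sum())
            for ci in picks:
                tl = templates[(gi, hom, int(ci))].size
                if rng.random() < full_length_prob or tl <= min_read_len:
                    s, e = 0, tl
                else:
                    ln = int(rng.integers(min_read_len, tl))
                    s, e = (0, ln) if rng.random() < 0.5 else (tl - ln, tl)
                has_bc = rng.random() >= error_model.barcode_loss_prob
                specs.append((gi, hom, int(ci), s, e, has_bc))
    if not specs:
        raise ValueError("no reads simulated; check weights/coverage")

    order = rng.permutation(len(specs))
    bcs = [_to_codes(b) for b in barcode_set]
    bcs_rc = [_to_codes(reverse_complement(b)) for b in barcode_set]

    def molecule(spec: tuple[int, str, int, int, int, bool]) -> np.ndarray:
        gi, hom, ci, s, e, has_bc = spec
        frag = templates[(gi, hom, ci)][s:e]
        if not has_bc:
            return frag
        parts = []
        if s == 0:
            parts.append(bcs[gi])
        parts.append(frag)
        if e == templates[(gi, hom, ci)].size:
            parts.append(bcs_rc[gi])
        return np.concatenate(parts)

    reads: list[SimRead] = []
    rows = []
    for k, idx in enumerate(order):
        spec = specs[idx]
        mol = molecule(spec)
        chimera = rng.random() < error_model.chimera_prob
        if chimera:
            partner = specs[int(rng.integers(len(specs)))]
            mol = np.concatenate([mol, molecule(partner)])
        seq_codes, quals = _apply_errors(mol, error_model, rng)
        gi, hom, ci, _, _, has_bc = spec
        rid = f"read_{k:06d}"
        reads.append(SimRead(rid, _to_str(seq_codes), quals,
                             genotypes[gi].cultivar_id, hom, ci, chimera,
                             has_bc, mol.size))
        rows.append((rid, genotypes[gi].cultivar_id, hom, ci, chimera,
                     has_bc, mol.size, seq_codes.size))
    truth = pd.DataFrame(rows, columns=["read_id", "cultivar", "homoeolog",
                                        "copy_index", "chimera",
                                        "barcode_present", "template_len",
                                        "read_len"])
    return reads, truth


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

DEFAULT_TRAITS: tuple[tuple[str, float, float], ...] = (
    # (trait, baseline mean, SD) in the units customary for European winter
    # wheat trials
    ("grain_yield_dt_ha", 95.0, 6.0),
    ("biomass_t_ha", 16.0, 1.5),
    ("thousand_kernel_weight_g", 46.0, 3.5),
    ("sedimentation_value", 40.0, 8.0),
    ("falling_number_s", 300.0, 40.0),
    ("kernels_per_spike", 45.0, 5.0),
    ("kernels_per_m2", 18_000.0, 2_000.0),
    ("spikes_per_m2", 550.0, 60.0),
    ("harvest_index", 0.50, 0.03),
    ("plant_height_cm", 85.0, 7.0),
    ("heading_date_d", 152.0, 3.0),
    ("nitrogen_use_efficiency", 1.0, 0.1),
    ("stripe_rust_pct", 85.0, 10.0),
    ("powdery_mildew_pct", 80.0, 10.0),
    ("crude_protein_pct", 13.0, 0.8),
    ("protein_yield_kg_ha", 1200.0, 90.0),
    ("radiation_use_efficiency_g_mj", 1.5, 0.15),
    ("radiation_interception_efficiency", 0.85, 0.05),
    ("green_canopy_duration_cd", 700.0, 60.0),
    ("nodal_root_angle_index", 1.0, 0.3),
)


@dataclass
class PhenoModel:
    """Additive group-effect model: value = baseline + effect + N(0, SD)."""

    traits: tuple[tuple[str, float, float], ...] = DEFAULT_TRAITS
    effects: Mapping[str, Mapping[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(sd <= 0 for _, _, sd in self.traits):
            raise ValueError("trait SDs must be > 0")

    @property
    def trait_names(self) -> list[str]:
        return [t for t, _, _ in self.traits]


def simulate_phenotypes(group_assignment, pheno_model: PhenoModel,
                        n_per_group: int | None = None,
                        seed: int = 0) -> pd.DataFrame:
    """Simulate a cultivar x trait table with planted group effects.

    ``group_assignment`` is either a mapping sample -> group, or an iterable
    of group labels combined with ``n_per_group`` (samples are then named
    ``<group>_<i>``).  Returns a DataFrame indexed by sample with a ``group``
    column followed by one numeric column per trait.
    """
    if isinstance(group_assignment, Mapping):
        assignment = dict(group_assignment)
    else:
        groups = list(group_assignment)
        if not groups:
            raise ValueError("no groups given")
        if n_per_group is None:
            raise ValueError("n_per_group required when passing group labels")
        assignment = {f"{g}_{i:03d}": g for g in groups
                      for i in range(n_per_group)}
    if not assignment:
        raise ValueError("empty group assignment")
    rng = np.random.default_rng(seed)
    samples = list(assignment)
    data = {"group": [assignment[s] for s in samples]}
    for trait, mean, sd in pheno_model.traits:
        eff = np.array([pheno_model.effects.get(assignment[s], {})
                        .get(trait, 0.0) for s in samples])
        data[trait] = mean + eff + rng.normal(0.0, sd, len(samples))
    return pd.DataFrame(data, index=pd.Index(samples, name="sample"))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_fastq(reads: Iterable[SimRead], path) -> None:
    """Write reads as Phred+33 FASTQ (byte-identical under identical seeds)."""
    with open(path, "w") as fh:
        for r in reads:
            q = "".join(chr(33 + int(x)) for x in r.qualities)
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{q}\n")


def write_fasta(refs: Iterable[HomoeologReference], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for ref in refs:
            fh.write(f">{ref.id}\n")
            for i in range(0, len(ref.sequence), width):
                fh.write(ref.sequence[i:i + width] + "\n")


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def write_genotype_config(genotypes: Sequence[CultivarGenotype], path) -> None:
    payload = [
        {"cultivar_id": g.cultivar_id,
         "copies": {h: [{"edits": [asdict(e) for e in c.edits],
                         "haplotype": c.haplotype, "weight": c.weight}
                        for c in cs] for h, cs in g.copies.items()}}
        for g in genotypes
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
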