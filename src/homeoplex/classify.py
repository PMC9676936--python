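"""Sequence-type assignment and cultivar grouping from variant matrices.

Consensus sequences are assigned to the closest labelled reference
(discarded below 99% identity, mirroring a strict best-BLAST-hit policy),
and cultivars are grouped by exact match of their variant vectors:
heterozygous calls compare as unordered allele pairs (zygosity, not phase,
defines a genotype group) and missing values match nothing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import edlib
import pandas as pd

from .synthgen import HomoeologReference

__all__ = ["SequenceTypeCall", "GroupAssignment", "sequence_type",
           "genotype_groups", "vrn_d1_groups"]


@dataclass
class SequenceTypeCall:
    sample_id: str
    homoeolog: str
    best_reference: str
    identity: float
    status: str  # assigned | discarded

    def __post_init__(self) -> None:
        if (self.status == "discarded") != (self.identity < 0.99):
            raise ValueError("discarded iff identity < 0.99")


@dataclass
class GroupAssignment:
    sample_id: str
    group: str
    vector: tuple


def sequence_type(consensus: str,
                  reference_panel: Mapping[str, HomoeologReference | str],
                  sample_id: str = "sample", homoeolog: str = "?",
                  min_identity: float = 0.99) -> SequenceTypeCall:
    """Best-hit assignment of a consensus against a labelled panel.

    Identity is global-alignment identity (1 - editdist / max length); ties
    break alphabetically by label; best hits below ``min_identity`` are
    discarded from downstream analyses.
    """
    if not consensus:
        raise ValueError("empty consensus")
    if not reference_panel:
        raise ValueError("empty reference panel")
    best_label, best_ident = None, -1.0
    for label in sorted(reference_panel):
        r = reference_panel[label]
        seq = r.sequence if isinstance(r, HomoeologReference) else r
        d = edlib.align(consensus, seq, mode="NW",
                        task="distance")["editDistance"]
        ident = 1.0 - d / max(len(consensus), len(seq))
        if ident > best_ident:
            best_label, best_ident = label, ident
    status = "assigned" if best_ident >= min_identity else "discarded"
    return SequenceTypeCall(sample_id, homoeolog, best_label, best_ident,
                            status)


def _normalise(entry) -> object:
    """Canonical form of one matrix entry: het pairs become frozensets."""
    if entry is None or (isinstance(entry, float) and pd.isna(entry)):
        return None
    s = str(entry)
    if "/" in s:
        return frozenset(s.split("/"))
    return s


def genotype_groups(matrix: pd.DataFrame, label_prefix: str = "G",
                    ) -> tuple[list[GroupAssignment], int]:
    """Group samples (rows) by exact match of their variant vectors.

    Heterozygous entries written ``X/Y`` compare unordered; missing entries
    (NaN/None) match nothing — not even another missing value — so a sample
    with any missing call forms its own group.  Group labels are ordered by
    descending group size, then first occurrence.
    """
    if matrix.empty:
        raise ValueError("empty variant matrix")
    keys: dict[str, object] = {}
    for sample in matrix.index:
        vec = tuple(_normalise(v) for v in matrix.loc[sample])
        # a missing value matches nothing: make the key unique to the sample
        keys[sample] = (sample, vec) if any(v is None for v in vec) else vec
    order: dict[object, list[str]] = {}
    for sample, key in keys.items():
        order.setdefault(key, []).append(sample)
    ranked = sorted(order.items(),
                    key=lambda kv: (-len(kv[1]),
                                    list(keys).index(kv[1][0])))
    assignments = []
    for gi, (key, samples) in enumerate(ranked, start=1):
        for s in samples:
            vec = key[1] if isinstance(key, tuple) and len(key) == 2 and \
                key[0] == s else key
            assignments.append(GroupAssignment(s, f"{label_prefix}{gi}",
                                               tuple(matrix.loc[s])))
    assignments.sort(key=lambda a: list(matrix.index).index(a.sample_id))
    return assignments, len(ranked)


def vrn_d1_groups(variants_by_sample: Mapping[str, Sequence[str]],
                  variant_keys: Sequence[str] = ("ins163", "del17", "snp5607"),
                  ) -> tuple[list[GroupAssignment], int]:
    """Group samples by presence/absence of the VRN-D1 variant trio
    (163 bp first-intron insertion, 17 bp deletion, intron-1 SNP); samples
    carrying none form the intact reference group."""
    rows = {s: [int(k in set(v)) for k in variant_keys]
            for s, v in variants_by_sample.items()}
    matrix = pd.DataFrame.from_dict(rows, orient="index",
                                    columns=list(variant_keys))
    return genotype_groups(matrix, label_prefix="D")
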