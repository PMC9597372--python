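"""Redundancy screening of nested PLM pairs.

Two PLMs are candidate-redundant when one motif is a strict substring of
the other.  A pair is *flagged* when their functional windows overlap
enough (Jaccard on inclusive integer offset sets >= 0.5) and they occur
in nearly the same genes (gene-set Jaccard >= 0.9).  Flagged pairs are
reported; collapsing is off by default — screening on real genomes shows
nested pairs to be a sub-percent fraction, so all PLMs are retained
unless explicitly collapsed.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .plm_core import PLMRecord

DEFAULT_GENE_THRESHOLD = 0.9
DEFAULT_WINDOW_THRESHOLD = 0.5


def jaccard_index(a, b) -> float:
    """|a ∩ b| / |a ∪ b| for finite sets; undefined when both are empty."""
    a, b = set(a), set(b)
    union = a | b
    if not union:
        raise ValueError("Jaccard index undefined for two empty sets")
    return len(a & b) / len(union)


def _window_set(plm: PLMRecord) -> frozenset[int]:
    lo, hi = plm.functional_window
    return frozenset(range(lo, hi + 1))


def find_inclusion_pairs(plms) -> list[tuple[PLMRecord, PLMRecord]]:
    """All ordered (short, long) pairs where one motif strictly contains the other."""
    pairs = []
    by_len = sorted(plms, key=lambda p: len(p.motif))
    for i, p in enumerate(by_len):
        for q in by_len[i:]:
            if len(p.motif) < len(q.motif) and p.motif in q.motif:
                pairs.append((p, q))
    return pairs


@dataclass(frozen=True)
class RedundantPair:
    short_plm: str
    long_plm: str
    window_jaccard: float
    gene_jaccard: float
    removable: str  # the lower-score member (tie -> shorter motif)


def flag_redundant(
    pairs,
    gene_threshold: float = DEFAULT_GENE_THRESHOLD,
    window_threshold: float = DEFAULT_WINDOW_THRESHOLD,
) -> list[RedundantPair]:
    """Flag nested pairs with coincident windows and near-identical gene sets."""
    out = []
    for p, q in pairs:
        wj = jaccard_index(_window_set(p), _window_set(q))
        if wj < window_threshold:
            continue
        if not (p.gene_set or q.gene_set):
            continue
        gj = jaccard_index(p.gene_set, q.gene_set)
        if gj < gene_threshold:
            continue
        if p.score < q.score:
            removable = p
        elif q.score < p.score:
            removable = q
        else:
            removable = p if len(p.motif) <= len(q.motif) else q
        out.append(RedundantPair(short_plm=p.motif, long_plm=q.motif,
                                 window_jaccard=wj, gene_jaccard=gj,
                                 removable=removable.motif))
    return out


def collapse(plms, flagged) -> list[PLMRecord]:
    """Drop every motif named removable in a flagged pair (idempotent)."""
    removable = {f.removable for f in flagged}
    return [p for p in plms if p.motif not in removable]


def pair_table(flagged) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "short_plm": [f.short_plm for f in flagged],
            "long_plm": [f.long_plm for f in flagged],
            "window_jaccard": [f.window_jaccard for f in flagged],
            "gene_jaccard": [f.gene_jaccard for f in flagged],
            "removable": [f.removable for f in flagged],
        }
    )
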