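"""Ground-truthed synthetic fixtures for the detection and network stacks.

Region generation emulates the single assumption the detector relies on:
an order-0 background with motifs overrepresented at an anchor-relative
offset.  Each plant overwrites one motif copy at ``center_offset`` plus a
uniform integer jitter in a Bernoulli-selected fraction of sequences and
records the truth; overlapping plants within one sequence are skipped and
logged so the truth stays unambiguous.  Block-matrix generation mirrors
the bipartite Bernoulli model the network module fits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .enrichment import AnnotationMap
from .genomic_io import FIVE_PRIME, ProximalRegionSet
from .plm_core import ALPHABET

logger = logging.getLogger(__name__)

UNIFORM_BACKGROUND = (0.25, 0.25, 0.25, 0.25)


@dataclass(frozen=True)
class PlantSpec:
    """One motif planted at center_offset ± jitter in a fraction of sequences."""

    motif: str
    center_offset: int
    jitter_radius: int = 0
    fraction: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.fraction <= 1.0):
            raise ValueError("fraction must be in [0, 1]")
        if self.jitter_radius < 0:
            raise ValueError("jitter_radius must be non-negative")
        if not set(self.motif.upper()) <= set(ALPHABET):
            raise ValueError(f"motif {self.motif!r} is not plain DNA")

    @classmethod
    def parse(cls, text: str) -> "PlantSpec":
        """Parse 'MOTIF:CENTER:JITTER:FRACTION' (e.g. 'TATAAATA:-35:2:0.3')."""
        motif, center, jitter, fraction = text.split(":")
        return cls(motif=motif.upper(), center_offset=int(center),
                   jitter_radius=int(jitter), fraction=float(fraction))


def generate_regions(
    n: int,
    upstream_extent: int,
    downstream_extent: int,
    background=UNIFORM_BACKGROUND,
    plants: list[PlantSpec] | None = None,
    seed: int | np.random.Generator = 0,
    side: str = FIVE_PRIME,
    gene_prefix: str = "gene",
) -> tuple[ProximalRegionSet, pd.DataFrame]:
    """I.i.d.-background windows with planted motifs, plus a truth table.

    The truth table records every realised plant as (gene_id, motif,
    offset) on the stored axis.  Fully reproducible from the seed.
    """
    probs = np.asarray(background, dtype=float)
    if probs.shape != (4,) or abs(probs.sum() - 1.0) > 1e-9 or (probs < 0).any():
        raise ValueError("background must be 4 probabilities summing to 1")
    plants = plants or []
    length = upstream_extent + downstream_extent + 1
    for spec in plants:
        lo = spec.center_offset - spec.jitter_radius
        hi = spec.center_offset + spec.jitter_radius + len(spec.motif) - 1
        if lo < -upstream_extent or hi > downstream_extent:
            raise ValueError(f"plant {spec.motif} does not fit the window "
                             f"for all jittered offsets")
    rng = np.random.default_rng(seed)
    base = np.frombuffer(ALPHABET.encode(), dtype=np.uint8)
    matrix = rng.choice(base, size=(n, length), p=probs)

    occupied: list[list[tuple[int, int]]] = [[] for _ in range(n)]
    truth_rows = []
    for spec in plants:
        selected = rng.random(n) < spec.fraction
        jitter = rng.integers(-spec.jitter_radius, spec.jitter_radius + 1, size=n)
        motif_bytes = np.frombuffer(spec.motif.encode(), dtype=np.uint8)
        for i in np.nonzero(selected)[0]:
            offset = int(spec.center_offset + jitter[i])
            start = offset + upstream_extent
            end = start + len(spec.motif) - 1
            if any(s <= end and start <= e for s, e in occupied[i]):
                logger.warning("plant %s at offset %d in sequence %d overlaps "
                               "an earlier plant; skipped", spec.motif, offset, i)
                continue
            matrix[i, start:end + 1] = motif_bytes
            occupied[i].append((start, end))
            truth_rows.append((f"{gene_prefix}{i:05d}", spec.motif, offset))

    records = [
        (f"{gene_prefix}{i:05d}", matrix[i].tobytes().decode("ascii"))
        for i in range(n)
    ]
    regions = ProximalRegionSet(
        side=side, upstream_extent=upstream_extent,
        downstream_extent=downstream_extent, records=records,
        orientation_note="synthetic; stored axis = sense axis",
    )
    truth = pd.DataFrame(truth_rows, columns=["gene_id", "motif", "offset"])
    return regions, truth


def generate_block_matrix(
    row_sizes,
    col_sizes,
    block_probs,
    seed: int | np.random.Generator = 0,
):
    """Bernoulli bipartite incidence with planted row/column blocks.

    Returns (matrix, row_labels, col_labels) where the labels are the
    planted partition memberships.
    """
    rng = np.random.default_rng(seed)
    block_probs = np.asarray(block_probs, dtype=float)
    row_labels = np.repeat(np.arange(len(row_sizes)), row_sizes)
    col_labels = np.repeat(np.arange(len(col_sizes)), col_sizes)
    probs = block_probs[np.ix_(row_labels, col_labels)]
    matrix = (rng.random(probs.shape) < probs).astype(np.int8)
    return matrix, row_labels, col_labels


def toy_annotation(
    genes,
    n_terms: int,
    concentration: float,
    seed: int | np.random.Generator = 0,
    focus_term: str = "T0000",
    focus_genes=None,
    background_rate: float = 0.1,
) -> AnnotationMap:
    """Random flat annotation with one term concentrated in a gene subset.

    The focus term covers each focus gene with probability
    ``concentration`` and each remaining gene with ``background_rate``;
    all other terms cover every gene at ``background_rate``.
    """
    genes = list(genes)
    if not genes:
        raise ValueError("gene list must be nonempty")
    rng = np.random.default_rng(seed)
    focus = set(focus_genes) if focus_genes is not None else set(genes[: len(genes) // 4])
    terms: dict[str, set[str]] = {}
    for t in range(n_terms):
        term_id = f"T{t:04d}"
        if term_id == focus_term:
            members = {
                g for g in genes
                if rng.random() < (concentration if g in focus else background_rate)
            }
        else:
            members = {g for g in genes if rng.random() < background_rate}
        if members:
            terms[term_id] = members
    return AnnotationMap(terms={t: frozenset(m) for t, m in terms.items()},
                         namespace="synthetic")
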