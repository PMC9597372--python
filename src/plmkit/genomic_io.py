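"""Extraction of oriented, anchor-aligned gene-proximal sequence windows.

The 5'-gene-proximal analysis anchors windows on the transcription start
site (TSS), the 3' analysis on the transcription termination site (TTS).
All windows of one set share a fixed length and a common orientation so
that a motif occurrence at stored index *j* means the same anchor-relative
position in every gene.

Coordinate conventions
----------------------
Offsets are signed integers with 0 at the anchor base.  On the *sense*
axis (5'->3' along the gene's coding strand) negative offsets lie upstream
of the anchor.  5' windows are stored in sense orientation.  3' windows
are stored in *antisense* orientation (forward-strand genes are
reverse-complemented) so that in stored coordinates the end farthest from
the gene again comes first; stored offset ``s`` maps back to the sense
TTS axis as ``-s``.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import gffutils

logger = logging.getLogger(__name__)

FIVE_PRIME = "five_prime"
THREE_PRIME = "three_prime"

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (N-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneModel:
    """Minimal per-gene coordinates needed to place proximal windows.

    ``tss`` and ``tts`` are 1-based genomic coordinates of the first and
    last transcribed base; on the minus strand ``tss >= tts``.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    tts: int
    has_5utr: bool
    has_3utr: bool

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.strand == "+" and self.tss > self.tts:
            raise ValueError(f"{self.gene_id}: tss > tts on + strand")
        if self.strand == "-" and self.tss < self.tts:
            raise ValueError(f"{self.gene_id}: tss < tts on - strand")


@dataclass
class ProximalRegionSet:
    """Fixed-length anchor-aligned windows, one per retained gene.

    ``upstream_extent``/``downstream_extent`` are in *stored* coordinates:
    the number of window positions before / after the anchor base in the
    orientation the sequences are stored in.  For 5' sets the stored axis
    equals the sense axis; for 3' sets stored offset ``s`` corresponds to
    sense offset ``-s`` (see module docstring).
    """

    side: str
    upstream_extent: int
    downstream_extent: int
    records: list[tuple[str, str]] = field(default_factory=list)
    orientation_note: str = ""
    n_dropped_no_utr: int = 0
    n_dropped_overrun: int = 0

    @property
    def window_length(self) -> int:
        return self.upstream_extent + self.downstream_extent + 1

    @property
    def n_sequences(self) -> int:
        return len(self.records)

    @property
    def gene_ids(self) -> list[str]:
        return [g for g, _ in self.records]

    def stored_to_sense(self, offset: int) -> int:
        """Map a stored-axis offset to the sense (gene-direction) axis."""
        return offset if self.side == FIVE_PRIME else -offset

    def validate(self) -> None:
        length = self.window_length
        seen: set[str] = set()
        for gene_id, seq in self.records:
            if len(seq) != length:
                raise ValueError(f"{gene_id}: window length {len(seq)} != {length}")
            if gene_id in seen:
                raise ValueError(f"duplicate gene_id {gene_id}")
            seen.add(gene_id)

    def to_table(self, path) -> None:
        """Write the two-column plain-text sequence table (gene_id, window)."""
        with open(path, "w") as fh:
            fh.write(f"# side={self.side}\tupstream={self.upstream_extent}\t"
                     f"downstream={self.downstream_extent}\n")
            for gene_id, seq in self.records:
                fh.write(f"{gene_id}\t{seq}\n")

    @classmethod
    def from_table(cls, path) -> "ProximalRegionSet":
        side, up, down = FIVE_PRIME, 0, 0
        records = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("#"):
                    for part in line[1:].split("\t"):
                        key, _, val = part.strip().partition("=")
                        if key == "side":
                            side = val
                        elif key == "upstream":
                            up = int(val)
                        elif key == "downstream":
                            down = int(val)
                    continue
                if line:
                    gene_id, seq = line.split("\t")
                    records.append((gene_id, seq.upper()))
        rs = cls(side=side, upstream_extent=up, downstream_extent=down,
                 records=records)
        rs.validate()
        return rs


def read_gene_models(annotation_source) -> list[GeneModel]:
    """Parse GFF3 into one :class:`GeneModel` per gene.

    ``annotation_source`` may be a path to a GFF3 file or the GFF3 text
    itself.  The anchor for genes with several transcripts is the most
    extreme annotated TSS (5'-most) and TTS (3'-most) over all mRNAs.
    Genes with no mRNA child are skipped with a warning.
    """
    source = str(annotation_source)
    from_string = "\n" in source or "\t" in source
    text = source if from_string else open(source).read()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line or line.startswith("#"):
            continue
        if len(line.split("\t")) != 9:
            raise ValueError(f"malformed GFF3 at line {lineno}: "
                             f"expected 9 tab-separated fields")
    try:
        db = gffutils.create_db(
            source, ":memory:", from_string=from_string,
            merge_strategy="create_unique", keep_order=True,
        )
    except Exception as exc:  # gffutils raises heterogeneous errors
        raise ValueError(f"malformed GFF3: {exc}") from exc

    models: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        mrnas = list(db.children(gene, featuretype="mRNA"))
        if not mrnas:
            logger.warning("gene %s has no mRNA feature; skipped", gene.id)
            continue
        has_5utr = any(
            True for m in mrnas for _ in db.children(m, featuretype="five_prime_UTR")
        )
        has_3utr = any(
            True for m in mrnas for _ in db.children(m, featuretype="three_prime_UTR")
        )
        starts = [m.start for m in mrnas]
        ends = [m.end for m in mrnas]
        if gene.strand == "+":
            tss, tts = min(starts), max(ends)
        elif gene.strand == "-":
            tss, tts = max(ends), min(starts)
        else:
            logger.warning("gene %s has strand %r; skipped", gene.id, gene.strand)
            continue
        gene_id = gene.attributes.get("ID", [gene.id])[0]
        models.append(GeneModel(gene_id=gene_id, chrom=gene.seqid,
                                strand=gene.strand, tss=tss, tts=tts,
                                has_5utr=has_5utr, has_3utr=has_3utr))
    return models


def _slice(genome, chrom: str, start1: int, end1: int) -> str:
    """1-based inclusive slice of a chromosome from a FASTA handle or dict."""
    seq = genome[chrom][start1 - 1:end1]
    return str(seq).upper()


def _chrom_len(genome, chrom: str) -> int:
    return len(genome[chrom])


def extract_proximal_sequences(
    genome,
    genes: list[GeneModel],
    side: str,
    upstream_extent: int,
    downstream_extent: int,
) -> ProximalRegionSet:
    """Cut anchor-centred windows out of a genome and orient them.

    Parameters
    ----------
    genome
        A ``pyfaidx.Fasta`` handle or any mapping of chromosome name to
        sequence supporting slicing (e.g. a plain dict of strings).
    side
        ``"five_prime"`` (TSS-anchored) or ``"three_prime"`` (TTS-anchored).
    upstream_extent, downstream_extent
        Extents on the *sense* axis: for the 5' side, bases upstream /
        downstream of the TSS; for the 3' side, bases inside the gene
        (upstream of the TTS) / beyond the TTS.

    Genes without the relevant annotated UTR are excluded (unreliable
    anchor); windows overrunning a chromosome end are dropped and counted.
    """
    if upstream_extent < 0 or downstream_extent < 0:
        raise ValueError("extents must be non-negative")
    if side not in (FIVE_PRIME, THREE_PRIME):
        raise ValueError(f"unknown side {side!r}")

    if side == FIVE_PRIME:
        stored_up, stored_down = upstream_extent, downstream_extent
        note = ("sense orientation; reverse-strand genes reverse-complemented; "
                "stored offset = sense offset relative to TSS")
    else:
        # 3' windows are standardized to the antisense orientation, so the
        # stored axis runs from the distal (downstream-of-gene) end toward
        # the gene body: stored offset s <-> sense offset -s.
        stored_up, stored_down = downstream_extent, upstream_extent
        note = ("antisense orientation; forward-strand genes reverse-"
                "complemented; stored offset s <-> sense TTS offset -s")

    rs = ProximalRegionSet(side=side, upstream_extent=stored_up,
                           downstream_extent=stored_down,
                           orientation_note=note)
    for gene in genes:
        if side == FIVE_PRIME and not gene.has_5utr:
            rs.n_dropped_no_utr += 1
            continue
        if side == THREE_PRIME and not gene.has_3utr:
            rs.n_dropped_no_utr += 1
            continue
        if gene.chrom not in genome:
            raise KeyError(f"chromosome {gene.chrom!r} (gene {gene.gene_id}) "
                           f"absent from genome")
        anchor = gene.tss if side == FIVE_PRIME else gene.tts
        fwd = gene.strand == "+"
        if side == FIVE_PRIME:
            if fwd:
                start, end, rc = anchor - upstream_extent, anchor + downstream_extent, False
            else:
                start, end, rc = anchor - downstream_extent, anchor + upstream_extent, True
        else:
            if fwd:
                start, end, rc = anchor - upstream_extent, anchor + downstream_extent, True
            else:
                start, end, rc = anchor - downstream_extent, anchor + upstream_extent, False
        if start < 1 or end > _chrom_len(genome, gene.chrom):
            logger.warning("gene %s window [%d,%d] overruns chromosome %s; "
                           "dropped", gene.gene_id, start, end, gene.chrom)
            rs.n_dropped_overrun += 1
            continue
        seq = _slice(genome, gene.chrom, start, end)
        if rc:
            seq = reverse_complement(seq)
        rs.records.append((gene.gene_id, seq))
    rs.validate()
    return rs


def load_fasta(path):
    """Open a genome FASTA for random access (pyfaidx-backed)."""
    import pyfaidx

    return pyfaidx.Fasta(str(path), as_raw=True, sequence_always_upper=True)
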