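"""Assignment of PLMs to transcription-factor and miRNA binding-site resources.

A PLM becomes a *tPLM* when its one-hot matrix is significantly close to
a library PWM (minimum per-column Euclidean distance over all >=4-column
alignments, both orientations; empirical p against the exhaustive
same-length k-mer null; BH-adjusted q < 0.05) or when it exactly matches
a curated ChIP-derived k-mer.  A *miPLM* is an 8-bp PLM found verbatim
inside a mature miRNA (U->T converted); full-length validation then
slides the whole miRNA over the genomic site allowing 0-5 mismatches.
PLMs with neither kind of evidence are *uPLMs*.  Independent positional
support can come from small chromatin footprints (BED intervals) falling
within the functional window extended by a 30-base flank.

The empirical-null significance replaces external PWM-comparison services
with an exact, enumerable null: every same-length k-mer is scored against
the PWM and the query's rank gives its p-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .enrichment import bh_adjust
from .genomic_io import FIVE_PRIME, GeneModel, reverse_complement
from .plm_core import ALPHABET, PLMRecord, _BASE_INDEX

MIRNA_LENGTH = 8          # only 8-bp PLMs are compared to miRNAs
SEED_REGION = (2, 8)      # miRNA 5'-seed, 1-based inclusive
CLEAVAGE_SITE = (10, 11)  # miRNA cleavage site, 1-based inclusive
DEFAULT_MAX_MISMATCH = 5
DEFAULT_FLANK = 30
MIN_OVERLAP = 4


# ---------------------------------------------------------------------------
# resource containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PWMEntry:
    matrix_id: str
    tf_name: str
    tf_family: str
    pfm: np.ndarray  # 4 x width, rows A,C,G,T, columns sum to 1


@dataclass
class PWMLibrary:
    entries: list[PWMEntry]

    def __post_init__(self) -> None:
        for e in self.entries:
            if e.pfm.shape[0] != 4 or e.pfm.shape[1] < MIN_OVERLAP:
                raise ValueError(f"{e.matrix_id}: PFM must be 4 x width>=4")
            if not np.allclose(e.pfm.sum(axis=0), 1.0, atol=1e-6):
                raise ValueError(f"{e.matrix_id}: PFM columns must sum to 1")


@dataclass
class KmerLibrary:
    """Curated exact-match k-mers per TF (e.g. top ChIP-seq k-mers)."""

    entries: list[tuple[str, str, frozenset[str]]]  # (tf, family, kmers)

    def lookup(self, motif: str) -> list[tuple[str, str]]:
        motif = motif.upper()
        return [(tf, fam) for tf, fam, kmers in self.entries if motif in kmers]


@dataclass
class MiRNALibrary:
    """Mature miRNAs with their DNA-converted (U->T) sequences."""

    entries: list[tuple[str, str, str]]  # (mirna_id, mature, dna)

    @classmethod
    def from_sequences(cls, pairs) -> "MiRNALibrary":
        entries = []
        for mirna_id, seq in pairs:
            seq = str(seq).upper()
            entries.append((mirna_id, seq, seq.replace("U", "T")))
        return cls(entries=entries)


def read_pwms(path, fmt: str = "jaspar", families: dict[str, str] | None = None) -> PWMLibrary:
    """Read a JASPAR-style or MEME-minimal motif file into a PWMLibrary."""
    from Bio import motifs

    families = families or {}
    entries = []
    with open(path) as fh:
        for m in motifs.parse(fh, "jaspar" if fmt == "jaspar" else "minimal"):
            counts = np.array([m.counts[b] for b in ALPHABET], dtype=float)
            col_sums = counts.sum(axis=0)
            col_sums[col_sums == 0] = 1.0
            matrix_id = getattr(m, "matrix_id", None) or m.name
            entries.append(PWMEntry(matrix_id=matrix_id, tf_name=m.name or matrix_id,
                                    tf_family=families.get(matrix_id, ""),
                                    pfm=counts / col_sums))
    return PWMLibrary(entries=entries)


def read_kmer_library(path) -> KmerLibrary:
    """Read a TSV with columns tf, family, kmer (one k-mer per line)."""
    table = pd.read_csv(path, sep="\t", comment="#",
                        names=["tf", "family", "kmer"], header=0)
    grouped: dict[tuple[str, str], set[str]] = {}
    for row in table.itertuples(index=False):
        grouped.setdefault((row.tf, row.family), set()).add(row.kmer.upper())
    return KmerLibrary(entries=[(tf, fam, frozenset(k))
                                for (tf, fam), k in grouped.items()])


def read_mirnas(path) -> MiRNALibrary:
    """Read mature miRNA sequences from FASTA (RNA or DNA alphabet)."""
    from Bio import SeqIO

    return MiRNALibrary.from_sequences(
        (rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
    )


def read_bed(path) -> list[tuple[str, int, int]]:
    """Read BED3+ intervals (0-based half-open) as (chrom, start, end)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            out.append((fields[0], int(fields[1]), int(fields[2])))
    return out


# ---------------------------------------------------------------------------
# PWM comparison
# ---------------------------------------------------------------------------

def kmer_to_pfm(motif: str) -> np.ndarray:
    """One-hot 4 x |motif| position frequency matrix."""
    motif = motif.upper()
    pfm = np.zeros((4, len(motif)), dtype=float)
    for j, ch in enumerate(motif):
        pfm[_BASE_INDEX[ch], j] = 1.0
    return pfm


def _rc_pfm(pfm: np.ndarray) -> np.ndarray:
    return pfm[::-1, ::-1]


def pwm_distance(query_pfm: np.ndarray, target_pfm: np.ndarray, offset: int) -> float:
    """Mean per-column Euclidean distance at one alignment offset.

    ``offset`` places query column 0 against target column ``offset``;
    the overlap must span at least 4 columns.
    """
    kq, kt = query_pfm.shape[1], target_pfm.shape[1]
    q_lo = max(0, -offset)
    q_hi = min(kq, kt - offset)
    if q_hi - q_lo < MIN_OVERLAP:
        raise ValueError(f"overlap at offset {offset} is below {MIN_OVERLAP} columns")
    q = query_pfm[:, q_lo:q_hi]
    t = target_pfm[:, q_lo + offset:q_hi + offset]
    return float(np.sqrt(((q - t) ** 2).sum(axis=0)).mean())


def best_alignment(query_pfm: np.ndarray, target_pfm: np.ndarray) -> tuple[float, int, str]:
    """Minimum alignment distance over all offsets and both query orientations."""
    kq, kt = query_pfm.shape[1], target_pfm.shape[1]
    best = (np.inf, 0, "+")
    for orient, q in (("+", query_pfm), ("-", _rc_pfm(query_pfm))):
        for offset in range(-(kq - MIN_OVERLAP), kt - MIN_OVERLAP + 1):
            try:
                d = pwm_distance(q, target_pfm, offset)
            except ValueError:
                continue
            if d < best[0]:
                best = (d, offset, orient)
    return best


def _letter_column_distances(target_pfm: np.ndarray) -> np.ndarray:
    """D[a, c] = Euclidean distance between one-hot letter a and target column c."""
    kt = target_pfm.shape[1]
    eye = np.eye(4)
    return np.sqrt(((eye[:, :, None] - target_pfm[None, :, :]) ** 2).sum(axis=1))


def catalog_distances(target_pfm: np.ndarray, k: int) -> np.ndarray:
    """best_alignment distance of every k-mer (4**k, base-4 code order) to a PWM.

    Vectorised equivalent of calling :func:`best_alignment` on each
    one-hot k-mer: per-column distances are table lookups, so the mean
    over an overlap is a sum of lookups over catalog codes.
    """
    kt = target_pfm.shape[1]
    D = _letter_column_distances(target_pfm)
    n = 4 ** k
    # letters[i, j] = j-th base index of k-mer with code i
    codes = np.arange(n)
    letters = np.empty((n, k), dtype=np.int64)
    for j in range(k):
        letters[:, k - 1 - j] = (codes >> (2 * j)) & 3
    rc_letters = 3 - letters[:, ::-1]
    best = np.full(n, np.inf)
    for lets in (letters, rc_letters):
        for offset in range(-(k - MIN_OVERLAP), kt - MIN_OVERLAP + 1):
            q_lo = max(0, -offset)
            q_hi = min(k, kt - offset)
            if q_hi - q_lo < MIN_OVERLAP:
                continue
            total = np.zeros(n)
            for i in range(q_lo, q_hi):
                total += D[lets[:, i], i + offset]
            np.minimum(best, total / (q_hi - q_lo), out=best)
    return best


def match_significance(
    query_motif: str, target_pfm: np.ndarray, distances: np.ndarray | None = None
) -> float:
    """Empirical p of a k-mer/PWM match against the exhaustive same-length null.

    ``p = (1 + #{k-mers with best distance <= query's}) / (1 + 4^k)``.
    Precomputed ``catalog_distances`` output may be passed to amortise
    the null over many queries.
    """
    from .plm_core import motif_code

    k = len(query_motif)
    if distances is None:
        distances = catalog_distances(target_pfm, k)
    d_query = distances[motif_code(query_motif)]
    return float((1 + int((distances <= d_query).sum())) / (1 + distances.size))


# ---------------------------------------------------------------------------
# assignment
# ---------------------------------------------------------------------------

@dataclass
class PLMAnnotation:
    motif: str
    assignment: str = "uPLM"  # tPLM | miPLM | both | uPLM
    tf_matches: list[dict] = field(default_factory=list)
    mirna_matches: list[dict] = field(default_factory=list)
    footprint_supported: bool = False

    def update_assignment(self) -> None:
        has_tf = bool(self.tf_matches)
        has_mi = bool(self.mirna_matches)
        self.assignment = ("both" if has_tf and has_mi
                           else "tPLM" if has_tf
                           else "miPLM" if has_mi
                           else "uPLM")


def assign_tplms(
    plms,
    pwm_lib: PWMLibrary | None = None,
    kmer_lib: KmerLibrary | None = None,
    q_threshold: float = 0.05,
    annotations: dict[str, PLMAnnotation] | None = None,
) -> dict[str, PLMAnnotation]:
    """tPLM evidence: BH-adjusted PWM match q < 0.05, or an exact k-mer hit.

    Q-values are adjusted jointly over every (PLM, matrix) test of the
    call.  Evidence rows record the matched TF, family, distance and q.
    """
    annotations = annotations if annotations is not None else {}
    for p in plms:
        annotations.setdefault(_motif_of(p), PLMAnnotation(motif=_motif_of(p)))
    motifs = [_motif_of(p) for p in plms]

    if pwm_lib is not None and pwm_lib.entries and motifs:
        tests = []  # (motif, entry, distance, p)
        by_len: dict[int, list[str]] = {}
        for m in motifs:
            by_len.setdefault(len(m), []).append(m)
        for entry in pwm_lib.entries:
            for k, group in by_len.items():
                dists = catalog_distances(entry.pfm, k)
                for m in group:
                    from .plm_core import motif_code

                    d = float(dists[motif_code(m)])
                    p = float((1 + int((dists <= d).sum())) / (1 + dists.size))
                    tests.append((m, entry, d, p))
        qvals = bh_adjust([t[3] for t in tests])
        for (m, entry, d, p), q in zip(tests, qvals):
            if q < q_threshold:
                annotations[m].tf_matches.append(
                    {"source": "pwm", "id": entry.matrix_id, "tf": entry.tf_name,
                     "family": entry.tf_family, "distance": d,
                     "p_value": p, "q_value": float(q)}
                )

    if kmer_lib is not None:
        for m in motifs:
            for tf, family in kmer_lib.lookup(m):
                annotations[m].tf_matches.append(
                    {"source": "kmer", "id": tf, "tf": tf, "family": family,
                     "distance": 0.0, "p_value": None, "q_value": None}
                )

    for ann in annotations.values():
        ann.update_assignment()
    return annotations


def assign_miplms(
    plms,
    mirna_lib: MiRNALibrary,
    annotations: dict[str, PLMAnnotation] | None = None,
) -> dict[str, PLMAnnotation]:
    """miPLM evidence: an 8-bp PLM found verbatim in a DNA-converted miRNA.

    Only motifs of length 8 are tested.  Match positions are recorded
    1-based within the miRNA (a hit on bases 2-9 has position 2).
    """
    annotations = annotations if annotations is not None else {}
    for p in plms:
        annotations.setdefault(_motif_of(p), PLMAnnotation(motif=_motif_of(p)))
    for p in plms:
        motif = _motif_of(p)
        if len(motif) != MIRNA_LENGTH:
            continue
        for mirna_id, _mature, dna in mirna_lib.entries:
            start = dna.find(motif)
            while start >= 0:
                annotations[motif].mirna_matches.append(
                    {"mirna_id": mirna_id, "position": start + 1,
                     "length": len(motif), "mirna_length": len(dna),
                     "full_length_valid": None, "mismatches": None}
                )
                start = dna.find(motif, start + 1)
    for ann in annotations.values():
        ann.update_assignment()
    return annotations


def _motif_of(p) -> str:
    return (p.motif if isinstance(p, PLMRecord) else str(p)).upper()


def validate_mirna_full_length(
    region_seq: str,
    occurrence_offset: int,
    mirna_dna: str,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    occurrence_length: int = MIRNA_LENGTH,
) -> tuple[bool, int]:
    """Best full-length ungapped miRNA placement over a miPLM site.

    Slides the DNA-converted miRNA and its reverse complement across every
    in-bounds placement covering the occurrence (``occurrence_offset`` is
    the 0-based start index in ``region_seq``); returns (valid, best
    Hamming mismatch count), valid iff best <= ``max_mismatch``.
    """
    region_seq = region_seq.upper()
    length = len(mirna_dna)
    occ_end = occurrence_offset + occurrence_length  # exclusive
    lo = max(0, occ_end - length)
    hi = min(len(region_seq) - length, occurrence_offset)
    best = length + 1
    for query in (mirna_dna.upper(), reverse_complement(mirna_dna.upper())):
        for start in range(lo, hi + 1):
            window = region_seq[start:start + length]
            mism = sum(a != b for a, b in zip(query, window))
            best = min(best, mism)
    return best <= max_mismatch, best


def mirna_coverage_profile(annotations, max_length: int | None = None) -> np.ndarray:
    """Per-base frequency of miRNA positions covered by miPLM matches.

    Position ``i`` (1-based, array index ``i-1``) gets the fraction of
    all recorded matches covering it.  Sub-regions of interest: the
    5'-seed (positions 2-8) and the cleavage site (positions 10-11).
    """
    matches = []
    source = annotations.values() if isinstance(annotations, dict) else annotations
    for ann in source:
        matches.extend(ann.mirna_matches if isinstance(ann, PLMAnnotation) else [ann])
    if max_length is None:
        max_length = max((m["mirna_length"] for m in matches), default=0)
    profile = np.zeros(max_length, dtype=float)
    for m in matches:
        profile[m["position"] - 1:m["position"] - 1 + m["length"]] += 1.0
    if matches:
        profile /= len(matches)
    return profile


# ---------------------------------------------------------------------------
# footprint overlap
# ---------------------------------------------------------------------------

def _sense_to_genomic(gene: GeneModel, side: str, offset: int) -> int:
    anchor = gene.tss if side == FIVE_PRIME else gene.tts
    return anchor + offset if gene.strand == "+" else anchor - offset


def overlap_with_intervals(
    plm: PLMRecord,
    genes: dict[str, GeneModel],
    intervals,
    flank: int = DEFAULT_FLANK,
    rule: str = "midpoint",
) -> tuple[bool, float]:
    """Positional support of a PLM by external footprint/peak intervals.

    For each containing gene, the functional window extended by ``flank``
    bases on both sides is mapped to genomic coordinates; the PLM is
    supported when at least one interval midpoint (``rule="midpoint"``)
    or any overlapping interval (``rule="overlap"``) falls inside,
    bounds inclusive.  Returns (supported, fraction of containing genes
    with support).  BED half-open input is converted to inclusive
    1-based coordinates.
    """
    if not plm.gene_set:
        return False, 0.0
    lo, hi = plm.functional_window
    lo, hi = lo - flank, hi + flank
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in intervals:
        by_chrom.setdefault(chrom, []).append((start + 1, end))  # inclusive 1-based
    n_supported = 0
    for gene_id in plm.gene_set:
        gene = genes.get(gene_id)
        if gene is None:
            continue
        a = _sense_to_genomic(gene, plm.side, lo)
        b = _sense_to_genomic(gene, plm.side, hi)
        g_lo, g_hi = min(a, b), max(a, b)
        hit = False
        for start, end in by_chrom.get(gene.chrom, ()):
            if rule == "midpoint":
                mid = (start + end) // 2
                hit = g_lo <= mid <= g_hi
            else:
                hit = start <= g_hi and g_lo <= end
            if hit:
                break
        n_supported += hit
    return n_supported > 0, n_supported / len(plm.gene_set)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def classify_plms(annotations) -> dict[str, int]:
    """Partition counts; the tPLM and miPLM columns both include 'both'.

    The identity ``tPLM + miPLM + uPLM - both = total`` always holds.
    """
    source = annotations.values() if isinstance(annotations, dict) else annotations
    counts = {"tPLM": 0, "miPLM": 0, "both": 0, "uPLM": 0}
    for ann in source:
        if ann.assignment in ("tPLM", "both"):
            counts["tPLM"] += 1
        if ann.assignment in ("miPLM", "both"):
            counts["miPLM"] += 1
        if ann.assignment == "both":
            counts["both"] += 1
        if ann.assignment == "uPLM":
            counts["uPLM"] += 1
    return counts


def annotation_table(annotations: dict[str, PLMAnnotation]) -> pd.DataFrame:
    rows = []
    for motif in sorted(annotations):
        ann = annotations[motif]
        rows.append(
            {
                "motif": motif,
                "assignment": ann.assignment,
                "n_tf_matches": len(ann.tf_matches),
                "n_mirna_matches": len(ann.mirna_matches),
                "tf_families": ";".join(sorted({m["family"] for m in ann.tf_matches
                                                if m["family"]})),
                "footprint_supported": ann.footprint_supported,
            }
        )
    return pd.DataFrame(rows)
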