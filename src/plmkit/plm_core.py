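"""Preferentially located motif (PLM) detection.

A PLM is a k-mer whose per-offset occurrence count, across a set of
anchor-aligned gene-proximal windows, rises above a 99% prediction band
at some position.  The band comes from an ordinary least-squares fit of
counts against offset over a *neutral region* — the window positions most
distal from the anchor, where no positional accumulation is expected.
Each detected PLM is summarised by

* its *preferential position* — the offset of maximum exceedance,
* its *functional window* — the contiguous run of band-exceeding offsets
  around that peak, and
* its *score* — observed count minus the band's upper bound at the
  preferential position (PLMs with score > 2 are retained by default).

The per-motif reference path (:func:`fit_neutral_model`,
:func:`band_upper`, :func:`detect_plm`) defines the semantics; the
catalog-scale path (:func:`find_plms`) vectorises the same computation
over one dense count table per motif length.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .genomic_io import FIVE_PRIME, THREE_PRIME, ProximalRegionSet

ALPHABET = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}

DEFAULT_CONFIDENCE = 0.99
DEFAULT_SCORE_MIN = 2.0
DEFAULT_NEUTRAL_LENGTH = 500


# ---------------------------------------------------------------------------
# motif catalog
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MotifCatalog:
    """Complete catalog of non-degenerate DNA k-mers for kmin <= k <= kmax."""

    kmin: int
    kmax: int
    motifs: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.motifs)

    def by_length(self, k: int) -> tuple[str, ...]:
        return tuple(m for m in self.motifs if len(m) == k)


def enumerate_kmers(kmin: int, kmax: int) -> MotifCatalog:
    """All DNA k-mers of each length in [kmin, kmax], lexicographic per length.

    The full 4-mer..8-mer catalog comprises 87,296 motifs.
    """
    if not (1 <= kmin <= kmax <= 12):
        raise ValueError(f"require 1 <= kmin <= kmax <= 12, got ({kmin}, {kmax})")
    motifs = [
        "".join(p)
        for k in range(kmin, kmax + 1)
        for p in itertools.product(ALPHABET, repeat=k)
    ]
    return MotifCatalog(kmin=kmin, kmax=kmax, motifs=tuple(motifs))


def motif_code(motif: str) -> int:
    """Base-4 integer encoding of a k-mer (A=0, C=1, G=2, T=3)."""
    code = 0
    for ch in motif.upper():
        code = code * 4 + _BASE_INDEX[ch]
    return code


def encode_sequences(records: list[tuple[str, str]]) -> np.ndarray:
    """Encode equal-length sequences as an int8 matrix; N (or any non-ACGT) = -1."""
    lut = np.full(256, -1, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        lut[ord(base)] = idx
        lut[ord(base.lower())] = idx
    rows = [np.frombuffer(seq.encode("ascii"), dtype=np.uint8) for _, seq in records]
    return lut[np.vstack(rows)] if rows else np.zeros((0, 0), dtype=np.int8)


def kmer_codes(encoded: np.ndarray, k: int) -> np.ndarray:
    """Sliding base-4 codes of all k-windows per row; -1 where a window has N."""
    n, length = encoded.shape
    n_off = length - k + 1
    codes = np.zeros((n, n_off), dtype=np.int64)
    bad = np.zeros((n, n_off), dtype=bool)
    for i in range(k):
        col = encoded[:, i:i + n_off]
        codes = codes * 4 + np.maximum(col, 0)
        bad |= col < 0
    codes[bad] = -1
    return codes


# ---------------------------------------------------------------------------
# positional tallies
# ---------------------------------------------------------------------------

@dataclass
class PositionalDistribution:
    """Per-offset occurrence counts of one motif over a region set."""

    motif: str
    side: str
    offsets: np.ndarray  # stored-axis offsets, ascending
    counts: np.ndarray   # same length as offsets
    n_sequences: int

    def count_at(self, offset: int) -> int:
        i = int(offset) - int(self.offsets[0])
        return int(self.counts[i])


class TallyResult:
    """Dense per-length count tables for a full catalog tally.

    ``tables[k]`` has shape (4**k, n_offsets_k); row index is the base-4
    motif code, column j the stored offset ``-upstream + j``.  The raw
    per-(sequence, offset) code matrices are kept for deriving
    PLM-containing gene sets without rescanning sequences.
    """

    def __init__(self, regions: ProximalRegionSet, kmin: int, kmax: int):
        self.side = regions.side
        self.upstream_extent = regions.upstream_extent
        self.downstream_extent = regions.downstream_extent
        self.n_sequences = regions.n_sequences
        self.gene_ids = list(regions.gene_ids)
        self.kmin = kmin
        self.kmax = kmax
        self.tables: dict[int, np.ndarray] = {}
        self.codes: dict[int, np.ndarray] = {}

    def offsets(self, k: int) -> np.ndarray:
        return np.arange(-self.upstream_extent, self.downstream_extent - k + 2)

    def distribution(self, motif: str) -> PositionalDistribution:
        k = len(motif)
        if k not in self.tables:
            raise KeyError(f"no tally for motif length {k}")
        return PositionalDistribution(
            motif=motif.upper(), side=self.side, offsets=self.offsets(k),
            counts=self.tables[k][motif_code(motif)].copy(),
            n_sequences=self.n_sequences,
        )


def tally_all(regions: ProximalRegionSet, catalog: MotifCatalog) -> TallyResult:
    """Count occurrences of every catalog motif at every start offset.

    Overlapping occurrences count; a sequence contributes at most one
    count per (motif, offset) cell by construction (one k-window per
    start).  K-windows containing N are skipped.
    """
    if regions.window_length <= catalog.kmax:
        raise ValueError("window_length must exceed kmax")
    result = TallyResult(regions, catalog.kmin, catalog.kmax)
    encoded = encode_sequences(regions.records)
    for k in range(catalog.kmin, catalog.kmax + 1):
        codes = kmer_codes(encoded, k)
        table = np.zeros((4 ** k, codes.shape[1]), dtype=np.int32)
        rows, cols = np.nonzero(codes >= 0)
        np.add.at(table, (codes[rows, cols], cols), 1)
        result.codes[k] = codes
        result.tables[k] = table
    return result


def positional_distribution(regions: ProximalRegionSet, motif: str) -> PositionalDistribution:
    """Tally a single motif (identical to the corresponding ``tally_all`` row)."""
    motif = motif.upper()
    k = len(motif)
    encoded = encode_sequences(regions.records)
    codes = kmer_codes(encoded, k)
    counts = (codes == motif_code(motif)).sum(axis=0).astype(np.int64)
    return PositionalDistribution(
        motif=motif, side=regions.side,
        offsets=np.arange(-regions.upstream_extent,
                          regions.downstream_extent - k + 2),
        counts=counts, n_sequences=regions.n_sequences,
    )


# ---------------------------------------------------------------------------
# neutral regression and prediction band
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NeutralFit:
    """OLS fit of counts vs offset over the neutral region."""

    intercept: float
    slope: float
    residual_sd: float
    n_points: int
    mean_x: float
    sxx: float
    neutral_interval: tuple[int, int]

    def predict(self, offset) -> float:
        return self.intercept + self.slope * np.asarray(offset, dtype=float)


def default_neutral_interval(
    upstream_extent: int, neutral_length: int = DEFAULT_NEUTRAL_LENGTH
) -> tuple[int, int]:
    """The ``neutral_length`` stored offsets most distal from the anchor.

    Stored windows start at their distal end on both sides, so the
    neutral region is always the first ``neutral_length`` positions.
    """
    return (-upstream_extent, -upstream_extent + neutral_length - 1)


def fit_neutral_model(
    dist: PositionalDistribution, neutral_interval: tuple[int, int]
) -> NeutralFit:
    """Ordinary least squares of counts against offset over the interval."""
    lo, hi = neutral_interval
    mask = (dist.offsets >= lo) & (dist.offsets <= hi)
    x = dist.offsets[mask].astype(float)
    y = dist.counts[mask].astype(float)
    n = x.size
    if n < 3:
        raise ValueError("neutral interval must contain at least 3 offsets")
    mean_x = x.mean()
    sxx = float(((x - mean_x) ** 2).sum())
    if sxx <= 0:
        raise ValueError("neutral interval has zero offset variance")
    slope = float(((x - mean_x) * (y - y.mean())).sum() / sxx)
    intercept = float(y.mean() - slope * mean_x)
    rss = float(((y - intercept - slope * x) ** 2).sum())
    residual_sd = float(np.sqrt(max(rss, 0.0) / (n - 2)))
    return NeutralFit(intercept=intercept, slope=slope, residual_sd=residual_sd,
                      n_points=int(n), mean_x=float(mean_x), sxx=sxx,
                      neutral_interval=(int(lo), int(hi)))


def band_upper(fit: NeutralFit, offset, confidence: float = DEFAULT_CONFIDENCE):
    """Upper limit of the two-sided prediction band for a new count.

    ``fit + t_{(1+c)/2, n-2} * sd * sqrt(1 + 1/n + (x - mean_x)^2 / Sxx)``.
    A prediction (not mean-response) band: the detector compares a single
    observed count at each offset against it.
    """
    if not (0.5 < confidence < 1.0):
        raise ValueError("confidence must be in (0.5, 1)")
    x = np.asarray(offset, dtype=float)
    tq = stats.t.ppf((1.0 + confidence) / 2.0, fit.n_points - 2)
    half = tq * fit.residual_sd * np.sqrt(
        1.0 + 1.0 / fit.n_points + (x - fit.mean_x) ** 2 / fit.sxx
    )
    out = fit.predict(x) + half
    return float(out) if np.isscalar(offset) or out.ndim == 0 else out


# ---------------------------------------------------------------------------
# PLM calling
# ---------------------------------------------------------------------------

@dataclass
class PLMRecord:
    """One detected preferentially located motif.

    Positions are on the distribution's stored axis when produced by
    :func:`detect_plm`; the pipeline maps 3'-side records to the sense
    TTS axis before reporting.
    """

    motif: str
    side: str
    preferential_position: int
    functional_window: tuple[int, int]
    score: float
    gene_set: frozenset[str] = field(default_factory=frozenset)
    group_label: str | None = None

    @property
    def k(self) -> int:
        return len(self.motif)


def detect_plm(
    dist: PositionalDistribution,
    fit: NeutralFit,
    study_interval: tuple[int, int],
    confidence: float = DEFAULT_CONFIDENCE,
) -> PLMRecord | None:
    """Call at most one PLM for a motif from its positional distribution.

    The exceedance set E collects study offsets whose count lies above the
    band's upper bound; the preferential position maximises the exceedance
    (ties -> smallest stored offset), the functional window is the maximal
    contiguous run of E containing it, and the score is the exceedance at
    the peak.  Returns ``None`` when E is empty.
    """
    lo, hi = study_interval
    nlo, nhi = fit.neutral_interval
    if not (hi < nlo or lo > nhi):
        raise ValueError("study interval must be disjoint from neutral interval")
    mask = (dist.offsets >= lo) & (dist.offsets <= hi)
    offsets = dist.offsets[mask]
    counts = dist.counts[mask].astype(float)
    diff = counts - band_upper(fit, offsets, confidence)
    exceed = diff > 0
    if not exceed.any():
        return None
    masked = np.where(exceed, diff, -np.inf)
    peak = int(np.argmax(masked))  # first max -> smallest offset on ties
    start = peak
    while start > 0 and exceed[start - 1]:
        start -= 1
    end = peak
    while end < exceed.size - 1 and exceed[end + 1]:
        end += 1
    return PLMRecord(
        motif=dist.motif, side=dist.side,
        preferential_position=int(offsets[peak]),
        functional_window=(int(offsets[start]), int(offsets[end])),
        score=float(diff[peak]),
    )


def select_by_score(plms, threshold: float = DEFAULT_SCORE_MIN):
    """Keep PLMs with score strictly above the threshold (default 2)."""
    return [p for p in plms if p.score > threshold]


def plm_gene_set(regions: ProximalRegionSet, plm: PLMRecord) -> frozenset[str]:
    """Genes whose window has >=1 occurrence starting inside the functional window.

    The record's window is interpreted on the axis it reports (sense for
    5', sense-TTS for 3'); occurrences are matched in the stored
    orientation and their start offsets mapped accordingly.
    """
    lo, hi = plm.functional_window
    if regions.side == THREE_PRIME:
        lo, hi = -hi, -lo  # sense -> stored
    motif = plm.motif.upper()
    genes = []
    for gene_id, seq in regions.records:
        start = 0
        while True:
            i = seq.find(motif, start)
            if i < 0:
                break
            if lo <= i - regions.upstream_extent <= hi:
                genes.append(gene_id)
                break
            start = i + 1
    return frozenset(genes)


# ---------------------------------------------------------------------------
# positional groups and composition summaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupScheme:
    """Labelled inclusive offset intervals on the reported position axis.

    Positions upstream of every interval get ``Us``, downstream ``Ds``,
    and gaps between non-juxtaposed intervals ``NA``.
    """

    name: str
    intervals: tuple[tuple[str, int, int], ...]  # (label, lo, hi) inclusive

    def __post_init__(self) -> None:
        prev_hi = None
        for _, lo, hi in self.intervals:
            if lo > hi:
                raise ValueError("interval lo > hi")
            if prev_hi is not None and lo <= prev_hi:
                raise ValueError("intervals must be sorted and non-overlapping")
            prev_hi = hi

    def assign(self, position: int) -> str:
        if position < self.intervals[0][1]:
            return "Us"
        if position > self.intervals[-1][2]:
            return "Ds"
        for label, lo, hi in self.intervals:
            if lo <= position <= hi:
                return label
        return "NA"


# Species presets; half-open published bounds converted to inclusive integers.
GROUP_SCHEMES: dict[str, GroupScheme] = {
    "at5p": GroupScheme("at5p", (("G1", -200, -51), ("G2", -50, -11), ("G3", -10, 19))),
    "at3p": GroupScheme("at3p", (("G1", -449, -175), ("G2", -59, -25), ("G3", -24, 10))),
    "zm5p": GroupScheme("zm5p", (("G1", -100, -51), ("G2", -50, -21), ("G3", -20, 19))),
    "zm3p": GroupScheme("zm3p", (("G1", -449, -225), ("G2", -74, -30), ("G3", -29, 10))),
}


def assign_group(plm: PLMRecord, scheme: GroupScheme) -> str:
    """Group label of the interval containing the preferential position."""
    return scheme.assign(plm.preferential_position)


def nucleotide_composition(plms) -> dict[str, float]:
    """Pooled A/C/G/T frequencies over the motif strings of the given PLMs."""
    counts = dict.fromkeys(ALPHABET, 0)
    total = 0
    for p in plms:
        motif = p.motif if isinstance(p, PLMRecord) else str(p)
        for ch in motif.upper():
            counts[ch] += 1
            total += 1
    if total == 0:
        return dict.fromkeys(ALPHABET, 0.0)
    return {b: counts[b] / total for b in ALPHABET}


# ---------------------------------------------------------------------------
# catalog-scale pipeline
# ---------------------------------------------------------------------------

def _vectorized_detect_k(
    table: np.ndarray,
    offsets: np.ndarray,
    neutral_interval: tuple[int, int],
    confidence: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Fit + band + exceedance for every motif of one length at once.

    Returns (detected_codes, peak_positions, window_lo, window_hi, scores)
    on the stored axis.
    """
    nlo, nhi = neutral_interval
    nmask = (offsets >= nlo) & (offsets <= nhi)
    x = offsets[nmask].astype(float)
    n = x.size
    if n < 3:
        raise ValueError("neutral interval must contain at least 3 offsets")
    mean_x = x.mean()
    xc = x - mean_x
    sxx = float((xc ** 2).sum())
    Y = table[:, nmask].astype(float)
    slope = (Y @ xc) / sxx
    intercept = Y.mean(axis=1) - slope * mean_x
    resid = Y - intercept[:, None] - slope[:, None] * x[None, :]
    sd = np.sqrt((resid ** 2).sum(axis=1) / (n - 2))

    smask = ~nmask
    so = offsets[smask].astype(float)
    tq = stats.t.ppf((1.0 + confidence) / 2.0, n - 2)
    leverage = np.sqrt(1.0 + 1.0 / n + (so - mean_x) ** 2 / sxx)
    band = (intercept[:, None] + slope[:, None] * so[None, :]
            + tq * sd[:, None] * leverage[None, :])
    diff = table[:, smask].astype(float) - band
    exceed = diff > 0
    det = np.nonzero(exceed.any(axis=1))[0]

    study_offsets = offsets[smask]
    peaks = np.empty(det.size, dtype=np.int64)
    wlo = np.empty(det.size, dtype=np.int64)
    whi = np.empty(det.size, dtype=np.int64)
    scores = np.empty(det.size, dtype=float)
    for i, code in enumerate(det):
        row = diff[code]
        erow = exceed[code]
        masked = np.where(erow, row, -np.inf)
        peak = int(np.argmax(masked))
        start = peak
        while start > 0 and erow[start - 1]:
            start -= 1
        end = peak
        while end < erow.size - 1 and erow[end + 1]:
            end += 1
        peaks[i] = study_offsets[peak]
        wlo[i] = study_offsets[start]
        whi[i] = study_offsets[end]
        scores[i] = row[peak]
    return det, peaks, wlo, whi, scores


def find_plms(
    regions: ProximalRegionSet,
    catalog: MotifCatalog | None = None,
    neutral_length: int = DEFAULT_NEUTRAL_LENGTH,
    confidence: float = DEFAULT_CONFIDENCE,
    score_min: float = DEFAULT_SCORE_MIN,
    scheme: GroupScheme | None = None,
    tally: TallyResult | None = None,
    with_gene_sets: bool = True,
) -> list[PLMRecord]:
    """Run the full detector: tally, fit, band, call, score-filter, annotate.

    3'-side records are reported on the sense TTS axis.  Records are
    ordered by motif length then lexicographically.
    """
    if catalog is None:
        catalog = enumerate_kmers(4, 8)
    if tally is None:
        tally = tally_all(regions, catalog)
    neutral = default_neutral_interval(regions.upstream_extent, neutral_length)
    out: list[PLMRecord] = []
    for k in range(catalog.kmin, catalog.kmax + 1):
        offsets = tally.offsets(k)
        det, peaks, wlo, whi, scores = _vectorized_detect_k(
            tally.tables[k], offsets, neutral, confidence
        )
        keep = scores > score_min
        kmers = np.array(catalog.by_length(k))
        order = np.argsort(det[keep])  # codes ascending = lexicographic
        for code, pp, lo, hi, sc in zip(
            det[keep][order], peaks[keep][order], wlo[keep][order],
            whi[keep][order], scores[keep][order],
        ):
            rec = PLMRecord(motif=str(kmers[code]), side=regions.side,
                            preferential_position=int(pp),
                            functional_window=(int(lo), int(hi)),
                            score=float(sc))
            if with_gene_sets:
                cols = np.nonzero((offsets >= lo) & (offsets <= hi))[0]
                hit = (tally.codes[k][:, cols] == motif_code(rec.motif)).any(axis=1)
                rec.gene_set = frozenset(
                    g for g, h in zip(tally.gene_ids, hit) if h
                )
            if regions.side == THREE_PRIME:
                slo, shi = rec.functional_window
                rec = replace(rec, preferential_position=-rec.preferential_position,
                              functional_window=(-shi, -slo))
            if scheme is not None:
                rec.group_label = assign_group(rec, scheme)
            out.append(rec)
    return out


def plm_table(plms) -> pd.DataFrame:
    """Flat PLM report: one row per record, windows inclusive."""
    return pd.DataFrame(
        {
            "motif": [p.motif for p in plms],
            "k": [p.k for p in plms],
            "side": [p.side for p in plms],
            "preferential_position": [p.preferential_position for p in plms],
            "window_start": [p.functional_window[0] for p in plms],
            "window_end": [p.functional_window[1] for p in plms],
            "score": [p.score for p in plms],
            "n_genes": [len(p.gene_set) for p in plms],
            "group_label": [p.group_label or "" for p in plms],
        }
    )


def gene_set_table(plms) -> pd.DataFrame:
    """Long-format motif -> gene_id membership table."""
    rows = [(p.motif, g) for p in plms for g in sorted(p.gene_set)]
    return pd.DataFrame(rows, columns=["motif", "gene_id"])
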