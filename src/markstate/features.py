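"""Localisation and extraction of per-gene histone-mark features.

Each gene gets a symmetric *input-field* of ``l`` bp centred on its TSS
(default 10 kb: 5 kb upstream, 5 kb downstream — an expanded promoter).
Called peaks are localised into that window as a piecewise-constant signal
``x`` of length ``l``: position ``i`` holds the enrichment (signalValue) of
the peak covering it, 0.0 where nothing was called. The per-mark feature is
a scalar collapse of ``x`` — by default its max, which keeps the strongest
epigenetic event wherever it falls inside the window instead of at a fixed
bin. Stacking marks gives the nonnegative feature matrix Phi (genes x marks).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree

from .io import GeneAnnotation, PeakRecord

logger = logging.getLogger(__name__)

#: The five core histone modifications, in the conventional order:
#: promoter mark, regulating mark, structural mark, then the two repressors.
CORE_MARKS = ("H3K4me3", "H3K4me1", "H3K36me3", "H3K9me3", "H3K27me3")

AGGREGATORS = ("max", "mean", "sum", "count")

DEFAULT_WINDOW = 10_000


@dataclass(frozen=True)
class InputField:
    """The genomic window assigned to a gene for featurisation.

    ``start`` is clipped at 0 for genes near the chromosome start; the
    localised vector is then zero-padded on the left so its length is
    always ``length``.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    length: int
    clipped: bool = False

    @property
    def pad(self) -> int:
        """Left zero-padding (bp lost to clipping at the chromosome start)."""
        return self.length - (self.end - self.start)


@dataclass
class LocalisedSignal:
    """Per-gene, per-mark enrichment signal over the input-field.

    ``x[i]`` is the signalValue of the peak covering input-field position
    ``i`` (genomic coordinate order), 0.0 where uncovered. ``n_peaks``
    counts distinct peaks overlapping the field (the ``count`` aggregator).
    """

    gene_id: str
    mark: str
    x: np.ndarray
    n_peaks: int = 0


def build_input_field(gene: GeneAnnotation, l: int = DEFAULT_WINDOW) -> InputField:
    """Build the symmetric l-bp window [tss - l/2, tss + l/2) for a gene.

    The window is strand-independent (it is symmetric about the TSS); the
    TSS itself must be strand-resolved in the annotation. Fields that would
    start before position 0 are clipped and flagged.
    """
    if l <= 0 or l % 2:
        raise ValueError(f"window length must be positive and even, got {l}")
    half = l // 2
    start = gene.tss - half
    clipped = start < 0
    if clipped:
        logger.warning(
            "input-field of gene %s clipped at chromosome start "
            "(tss=%d < l/2=%d); vector will be zero-padded",
            gene.gene_id, gene.tss, half,
        )
        start = 0
    return InputField(
        gene_id=gene.gene_id,
        chrom=gene.chrom,
        start=start,
        end=gene.tss + half,
        length=l,
        clipped=clipped,
    )


def localise(peaks: Sequence[PeakRecord], field: InputField, mark: str = "") -> LocalisedSignal:
    """Project peak enrichments onto a gene's input-field.

    Where two called peaks overlap at a position the larger signalValue
    wins (this cannot change the downstream max feature). Peaks on other
    chromosomes or entirely outside the field contribute nothing.
    """
    x = np.zeros(field.length, dtype=float)
    n = 0
    for p in peaks:
        if p.chrom != field.chrom or p.end <= field.start or p.start >= field.end:
            continue
        n += 1
        lo = max(p.start, field.start) - field.start + field.pad
        hi = min(p.end, field.end) - field.start + field.pad
        np.maximum(x[lo:hi], p.signal_value, out=x[lo:hi])
    return LocalisedSignal(gene_id=field.gene_id, mark=mark, x=x, n_peaks=n)


def extract_feature(signal: LocalisedSignal, aggregator: str = "max") -> float:
    """Collapse a localised signal to a scalar feature.

    ``max`` is the default (the strongest epigenetic event in the window);
    ``mean``/``sum``/``count`` are the sensitivity alternatives — mean and
    sum over all l positions, count of distinct overlapping peaks.
    """
    if aggregator == "max":
        return float(signal.x.max(initial=0.0))
    if aggregator == "mean":
        return float(signal.x.mean())
    if aggregator == "sum":
        return float(signal.x.sum())
    if aggregator == "count":
        return float(signal.n_peaks)
    raise ValueError(f"unknown aggregator {aggregator!r}; expected one of {AGGREGATORS}")


@dataclass
class FeatureMatrix:
    """Phi: n genes x m marks of nonnegative scalar enrichment features."""

    gene_ids: list[str]
    marks: list[str]
    Phi: np.ndarray
    dialects: Mapping[str, str] | None = None
    window: int | None = DEFAULT_WINDOW
    aggregator: str = "max"

    def __post_init__(self) -> None:
        self.Phi = np.asarray(self.Phi, dtype=float)
        if self.Phi.shape != (len(self.gene_ids), len(self.marks)):
            raise ValueError(
                f"Phi shape {self.Phi.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.marks)} marks"
            )

    def column(self, mark: str) -> np.ndarray:
        return self.Phi[:, self.marks.index(mark)]

    def subset(self, idx: np.ndarray) -> "FeatureMatrix":
        gene_ids = [self.gene_ids[i] for i in np.asarray(idx)]
        return FeatureMatrix(
            gene_ids=gene_ids, marks=list(self.marks), Phi=self.Phi[idx],
            dialects=self.dialects, window=self.window, aggregator=self.aggregator,
        )


def order_marks(marks: Sequence[str]) -> list[str]:
    """Order marks canonically: the five core marks first in their
    conventional order, any others after in input order."""
    marks = list(marks)
    core = [m for m in CORE_MARKS if m in marks]
    rest = [m for m in marks if m not in CORE_MARKS]
    return core + rest


def _peak_index(peaks: Sequence[PeakRecord]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for p in peaks:
        trees.setdefault(p.chrom, IntervalTree()).addi(p.start, p.end, p.signal_value)
    return trees


def _aggregate_overlaps(
    overlaps: list[tuple[int, int, float]], field: InputField, aggregator: str
) -> float:
    """Collapse the peaks overlapping one field without building the length-l
    vector: max/count read the overlap list directly; mean/sum sweep the
    clipped-interval breakpoints so memory stays proportional to #peaks."""
    if aggregator == "max":
        return max((sig for _, _, sig in overlaps), default=0.0)
    if aggregator == "count":
        return float(len(overlaps))
    clipped = [
        (max(s, field.start), min(e, field.end), sig) for s, e, sig in overlaps
    ]
    points = sorted({c for s, e, _ in clipped for c in (s, e)})
    total = 0.0
    for lo, hi in zip(points[:-1], points[1:]):
        seg = max((sig for s, e, sig in clipped if s <= lo and e >= hi), default=0.0)
        total += seg * (hi - lo)
    if aggregator == "sum":
        return total
    if aggregator == "mean":
        return total / field.length
    raise ValueError(f"unknown aggregator {aggregator!r}; expected one of {AGGREGATORS}")


def build_feature_matrix(
    genes: Sequence[GeneAnnotation],
    peak_tracks: Mapping[str, tuple[str, Sequence[PeakRecord]]],
    l: int = DEFAULT_WINDOW,
    aggregator: str = "max",
    mark_order: Sequence[str] | None = None,
) -> FeatureMatrix:
    """Featurise all genes against one peak track per mark.

    Parameters
    ----------
    genes : gene annotations (nonempty)
    peak_tracks : mark -> (dialect, peaks); the dialect is recorded as
        provenance in the output
    l : input-field length in bp
    aggregator : max (default) | mean | sum | count

    Uses an interval index per mark, so memory is proportional to the peaks
    and the n x m output, never the n x l localised vectors.
    """
    if not peak_tracks:
        raise ValueError("at least one mark's peak track is required")
    if not genes:
        raise ValueError("gene list is empty")
    if aggregator not in AGGREGATORS:
        raise ValueError(f"unknown aggregator {aggregator!r}; expected one of {AGGREGATORS}")
    marks = list(mark_order) if mark_order is not None else order_marks(peak_tracks)
    fields = [build_input_field(g, l) for g in genes]
    Phi = np.zeros((len(genes), len(marks)), dtype=float)
    for j, mark in enumerate(marks):
        dialect, peaks = peak_tracks[mark]
        trees = _peak_index(peaks)
        for i, field in enumerate(fields):
            tree = trees.get(field.chrom)
            if tree is None:
                continue
            overlaps = [(iv.begin, iv.end, iv.data) for iv in tree.overlap(field.start, field.end)]
            if overlaps:
                Phi[i, j] = _aggregate_overlaps(overlaps, field, aggregator)
    return FeatureMatrix(
        gene_ids=[g.gene_id for g in genes],
        marks=marks,
        Phi=Phi,
        dialects={m: peak_tracks[m][0] for m in marks},
        window=l,
        aggregator=aggregator,
    )
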