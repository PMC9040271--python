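"""Readers and writers for the external file formats the pipeline consumes.

Peak calls arrive in the three ENCODE BED dialects produced by MACS2-style
callers (narrowPeak = BED6+4, broadPeak = BED6+3, gappedPeak = BED12+3).
Coordinates are 0-based half-open throughout; the ``signalValue`` column is
the per-peak enrichment score that all downstream featurisation uses.
Gene/TSS annotations, expression tables (RPKM), ChromHMM emission matrices
and the package's own feature-matrix table are plain TSV/CSV.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DIALECTS = ("narrow", "broad", "gapped")

# 1-based signalValue column and total column count per dialect
_DIALECT_COLUMNS = {"narrow": 10, "broad": 9, "gapped": 15}
_SIGNAL_COLUMN = {"narrow": 6, "broad": 6, "gapped": 12}  # 0-based
_PVALUE_COLUMN = {"narrow": 7, "broad": 7, "gapped": 13}
_QVALUE_COLUMN = {"narrow": 8, "broad": 8, "gapped": 14}


class PeakParseError(ValueError):
    """A peak BED line violates its dialect's column contract."""


class ValidationError(ValueError):
    """An input table violates a documented invariant."""


@dataclass
class PeakRecord:
    """One called peak: a genomic interval with an enrichment score.

    ``signal_value`` is the ENCODE ``signalValue`` field — the de-noised
    enrichment that the localisation step spreads over the peak's extent.
    ``p_value``/``q_value`` are -log10 scores, -1 when absent. ``extra``
    carries dialect-specific trailing fields (narrowPeak point-source
    offset, gappedPeak block structure) untouched.
    """

    chrom: str
    start: int
    end: int
    name: str = "."
    score: int = 0
    strand: str = "."
    signal_value: float = 0.0
    p_value: float = -1.0
    q_value: float = -1.0
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValidationError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.signal_value < 0:
            raise ValidationError(f"negative signalValue {self.signal_value}")


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene identified by its strand-resolved TSS position (0-based)."""

    gene_id: str
    chrom: str
    tss: int
    strand: str


class ExpressionTable(dict):
    """Mapping gene_id -> RPKM abundance (nonnegative reals)."""

    def __init__(self, values: Mapping[str, float] | None = None):
        super().__init__()
        if values:
            for g, t in values.items():
                if t < 0:
                    raise ValidationError(f"negative RPKM {t} for gene {g}")
                self[g] = float(t)


@dataclass
class EmissionMatrix:
    """A ChromHMM-style emission table: states x marks probabilities."""

    states: list[str]
    marks: list[str]
    E: np.ndarray
    groups: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.E = np.asarray(self.E, dtype=float)
        if self.E.shape != (len(self.states), len(self.marks)):
            raise ValidationError(
                f"emission matrix shape {self.E.shape} does not match "
                f"{len(self.states)} states x {len(self.marks)} marks"
            )
        if np.any(self.E < 0) or np.any(self.E > 1):
            bad = self.E[(self.E < 0) | (self.E > 1)].flat[0]
            raise ValidationError(f"emission probability {bad} outside [0, 1]")
        if self.groups is not None:
            unknown = set(self.groups) - set(self.states)
            if unknown:
                raise ValidationError(
                    f"group table references unknown states: {sorted(unknown)}"
                )

    def reorder_marks(self, marks: Sequence[str]) -> "EmissionMatrix":
        """Return a copy with mark columns permuted into the given order."""
        missing = [m for m in marks if m not in self.marks]
        if missing:
            raise ValidationError(f"emission matrix lacks marks {missing}")
        idx = [self.marks.index(m) for m in marks]
        return EmissionMatrix(
            states=list(self.states),
            marks=list(marks),
            E=self.E[:, idx],
            groups=dict(self.groups) if self.groups else None,
        )


def _is_header(line: str) -> bool:
    return line.startswith(("track", "browser", "#"))


def read_peaks(path: str | Path, dialect: str) -> list[PeakRecord]:
    """Parse an ENCODE peak BED file of the given dialect.

    Parameters
    ----------
    path : file path
    dialect : one of "narrow", "broad", "gapped"

    Header lines (``track``/``browser``/``#``) are skipped. Every data line
    must have the dialect's exact column count; violations raise
    :class:`PeakParseError` naming the line number.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown peak dialect {dialect!r}; expected one of {DIALECTS}")
    ncols = _DIALECT_COLUMNS[dialect]
    records: list[PeakRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if _is_header(line):
                logger.debug("skipping header line %d of %s", lineno, path)
                continue
            fields = line.split("\t")
            if len(fields) != ncols:
                raise PeakParseError(
                    f"{path}:{lineno}: expected {ncols} columns for dialect "
                    f"{dialect!r}, got {len(fields)}"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise PeakParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end or start < 0:
                raise PeakParseError(
                    f"{path}:{lineno}: invalid interval [{start}, {end})"
                )
            try:
                signal = float(fields[_SIGNAL_COLUMN[dialect]])
                pval = float(fields[_PVALUE_COLUMN[dialect]])
                qval = float(fields[_QVALUE_COLUMN[dialect]])
                score = int(float(fields[4]))
            except ValueError as exc:
                raise PeakParseError(f"{path}:{lineno}: non-numeric field") from exc
            extra: dict = {}
            if dialect == "narrow":
                extra["peak"] = int(fields[9])
            elif dialect == "gapped":
                extra["thick_start"] = int(fields[6])
                extra["thick_end"] = int(fields[7])
                extra["item_rgb"] = fields[8]
                extra["block_count"] = int(fields[9])
                extra["block_sizes"] = fields[10]
                extra["block_starts"] = fields[11]
            records.append(
                PeakRecord(
                    chrom=fields[0],
                    start=start,
                    end=end,
                    name=fields[3],
                    score=score,
                    strand=fields[5],
                    signal_value=signal,
                    p_value=pval,
                    q_value=qval,
                    extra=extra,
                )
            )
    return records


def write_peaks(records: Sequence[PeakRecord], path: str | Path, dialect: str) -> None:
    """Write peaks in the given ENCODE dialect (round-trips with read_peaks)."""
    if dialect not in DIALECTS:
        raise ValueError(f"unknown peak dialect {dialect!r}; expected one of {DIALECTS}")
    with open(path, "w") as fh:
        for r in records:
            base = [r.chrom, str(r.start), str(r.end), r.name, str(r.score), r.strand]
            stats = [repr(float(r.signal_value)), repr(float(r.p_value)), repr(float(r.q_value))]
            if dialect == "narrow":
                fields = base + stats + [str(r.extra.get("peak", -1))]
            elif dialect == "broad":
                fields = base + stats
            else:  # gapped: synthesise a single-block BED12 when blocks absent
                length = r.end - r.start
                fields = base + [
                    str(r.extra.get("thick_start", r.start)),
                    str(r.extra.get("thick_end", r.end)),
                    str(r.extra.get("item_rgb", "0")),
                    str(r.extra.get("block_count", 1)),
                    str(r.extra.get("block_sizes", f"{length},")),
                    str(r.extra.get("block_starts", "0,")),
                ] + stats
            fh.write("\t".join(fields) + "\n")


def read_genes(
    path: str | Path,
    gene_id_col: str = "gene_id",
    chrom_col: str = "chrom",
    tss_col: str = "tss",
    strand_col: str = "strand",
) -> list[GeneAnnotation]:
    """Read a gene/TSS annotation table (TSV or CSV with header).

    The TSS must already be strand-resolved: for minus-strand genes the
    annotation supplies the transcription start, not the interval minimum.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    for col in (gene_id_col, chrom_col, tss_col, strand_col):
        if col not in df.columns:
            raise ValidationError(f"gene table missing column {col!r}")
    dup = df[gene_id_col][df[gene_id_col].duplicated()]
    if not dup.empty:
        raise ValidationError(f"duplicate gene_id(s): {sorted(set(dup))}")
    genes = []
    for _, row in df.iterrows():
        strand = str(row[strand_col])
        if strand not in ("+", "-"):
            raise ValidationError(
                f"gene {row[gene_id_col]}: strand {strand!r} not in {{+, -}}"
            )
        tss = int(row[tss_col])
        if tss < 0:
            raise ValidationError(f"gene {row[gene_id_col]}: negative TSS {tss}")
        genes.append(
            GeneAnnotation(
                gene_id=str(row[gene_id_col]),
                chrom=str(row[chrom_col]),
                tss=tss,
                strand=strand,
            )
        )
    return genes


def write_genes(genes: Sequence[GeneAnnotation], path: str | Path) -> None:
    pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "chrom": [g.chrom for g in genes],
            "tss": [g.tss for g in genes],
            "strand": [g.strand for g in genes],
        }
    ).to_csv(path, sep="\t", index=False)


def read_expression(path: str | Path) -> ExpressionTable:
    """Read a two-column gene_id / RPKM table; negative values are rejected."""
    df = pd.read_csv(path, sep=None, engine="python")
    if df.shape[1] < 2:
        raise ValidationError("expression table needs gene_id and rpkm columns")
    ids, vals = df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(float)
    if (vals < 0).any():
        bad = ids[vals < 0].iloc[0]
        raise ValidationError(f"negative RPKM for gene {bad}")
    return ExpressionTable(dict(zip(ids, vals)))


def write_expression(expr: Mapping[str, float], path: str | Path) -> None:
    pd.DataFrame(
        {"gene_id": list(expr.keys()), "rpkm": list(expr.values())}
    ).to_csv(path, sep="\t", index=False)


def read_emissions(
    path: str | Path, groups_path: str | Path | None = None
) -> EmissionMatrix:
    """Read a states x marks emission-probability table.

    Expected orientation: one row per chromatin state (labels in the first
    column), one column per histone mark (names in the header). The optional
    groups file is a two-column state -> group table.
    """
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    groups = None
    if groups_path is not None:
        gdf = pd.read_csv(groups_path, sep=None, engine="python")
        groups = dict(zip(gdf.iloc[:, 0].astype(str), gdf.iloc[:, 1].astype(str)))
    return EmissionMatrix(
        states=[str(s) for s in df.index],
        marks=[str(m) for m in df.columns],
        E=df.to_numpy(dtype=float),
        groups=groups,
    )


def write_feature_matrix(fm, path: str | Path, sidecar: bool = True) -> None:
    """Write a feature matrix as genes x marks TSV plus a JSON sidecar.

    The sidecar records the peak dialect used per mark and the featurisation
    parameters, so a fitted model can be audited against its inputs.
    """
    df = pd.DataFrame(fm.Phi, index=fm.gene_ids, columns=fm.marks)
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")
    if sidecar:
        meta = {
            "marks": list(fm.marks),
            "dialects": dict(fm.dialects or {}),
            "window": fm.window,
            "aggregator": fm.aggregator,
        }
        Path(str(path) + ".json").write_text(json.dumps(meta, indent=2))


def read_feature_matrix(path: str | Path):
    """Read a feature matrix written by :func:`write_feature_matrix`."""
    from .features import FeatureMatrix  # local import avoids a cycle

    df = pd.read_csv(path, sep="\t", index_col=0)
    meta_path = Path(str(path) + ".json")
    dialects, window, aggregator = None, None, "max"
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        dialects = meta.get("dialects")
        window = meta.get("window")
        aggregator = meta.get("aggregator", "max")
    return FeatureMatrix(
        gene_ids=[str(g) for g in df.index],
        marks=[str(m) for m in df.columns],
        Phi=df.to_numpy(dtype=float),
        dialects=dialects,
        window=window,
        aggregator=aggregator,
    )
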