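"""Self-contained synthetic data with planted statistical structure.

The generator emulates the shapes of consolidated epigenome data: sparse
called peaks with positive, right-skewed (log-normal) enrichment scores
for five core histone marks; a roughly bimodal nonnegative expression
distribution (a near-zero OFF component plus a log-normal ON component);
and a planted monotone link between activator/repressor mark enrichment
and the expression class, via a ground-truth logistic model.

For each gene a latent ON/OFF class is drawn from the planted logistic
model applied to its planted per-mark enrichments; peaks realising those
enrichments are materialised inside the gene's 10 kb TSS window (plus
occasional background peaks between windows), and expression is drawn
from the class-conditional mixture so that median-thresholding recovers
the latent class with high probability. Every mark is emitted in all
three peak dialects; dialects listed in ``noise_dialects`` get signal
values re-drawn independently of the class, which plants a format-
selection problem.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import expit

from .features import CORE_MARKS, DEFAULT_WINDOW, build_feature_matrix, FeatureMatrix
from .io import (
    ExpressionTable,
    GeneAnnotation,
    PeakRecord,
    write_expression,
    write_genes,
    write_peaks,
)

_DIALECT_EXT = {"narrow": "narrowPeak", "broad": "broadPeak", "gapped": "gappedPeak"}


@dataclass
class FixtureSpec:
    """Study conditions for one synthetic epigenome.

    Defaults plant a moderately hard problem: weight magnitudes sized so a
    logistic fit on the extracted features lands in the high-0.8s AUROC
    regime typical of real consolidated epigenomes, with the two repressor
    marks carrying negative weights and a negative bias (genes default to
    inactive absent epigenetic signal).
    """

    n_genes: int = 2000
    marks: tuple[str, ...] = CORE_MARKS
    window: int = DEFAULT_WINDOW
    chrom: str = "chr1"
    chrom_length: int | None = None  # None: sized automatically
    gene_spacing: int = 15_000  # TSS-to-TSS distance; must exceed window
    # ground-truth logistic model over planted enrichments
    w_star: tuple[float, ...] = (0.9, 0.35, 0.55, -0.5, -0.9)
    b_star: float = -1.0
    # per-mark peak occurrence rate inside the window
    peak_rate: tuple[float, ...] = (0.65, 0.60, 0.55, 0.45, 0.50)
    # log-normal enrichment (signalValue) parameters
    enrich_mu: float = 0.8
    enrich_sigma: float = 0.6
    peak_length: tuple[int, int] = (300, 2000)
    background_rate: float = 0.3  # chance of a stray peak in each inter-window gap
    # expression mixture: OFF ~ Exp(scale), ON ~ LogNormal(mu, sigma)
    expr_off_scale: float = 0.3
    expr_on_mu: float = 3.0
    expr_on_sigma: float = 0.8
    expr_noise: float = 0.0  # prob. of drawing expression from the wrong component
    noise_dialects: tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        m = len(self.marks)
        if len(self.w_star) != m or len(self.peak_rate) != m:
            raise ValueError("w_star and peak_rate must have one entry per mark")
        if self.gene_spacing <= self.window:
            raise ValueError(
                f"gene_spacing {self.gene_spacing} must exceed the window "
                f"{self.window} so input-fields cannot overlap"
            )
        if self.peak_length[1] >= self.window:
            raise ValueError("peak length must be below the window size")


@dataclass
class SyntheticDataset:
    """Generated tracks plus the ground truth that produced them."""

    spec: FixtureSpec
    genes: list[GeneAnnotation]
    expression: ExpressionTable
    peaks: dict  # mark -> dialect -> list[PeakRecord]
    truth: dict  # w_star, b_star, phi_star, prob, latent_class

    def featurise(self, dialect: str = "narrow", aggregator: str = "max") -> FeatureMatrix:
        tracks = {m: (dialect, self.peaks[m][dialect]) for m in self.spec.marks}
        return build_feature_matrix(
            self.genes, tracks, l=self.spec.window, aggregator=aggregator,
            mark_order=self.spec.marks,
        )

    def feature_candidates(self, aggregator: str = "max") -> dict:
        """mark -> dialect -> feature column, for peak-format selection."""
        out: dict[str, dict[str, np.ndarray]] = {m: {} for m in self.spec.marks}
        for dialect in _DIALECT_EXT:
            fm = self.featurise(dialect, aggregator)
            for m in self.spec.marks:
                out[m][dialect] = fm.column(m)
        return out

    @property
    def latent_class(self) -> np.ndarray:
        return np.asarray(self.truth["latent_class"], dtype=int)

    @property
    def phi_star(self) -> np.ndarray:
        return np.asarray(self.truth["phi_star"], dtype=float)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_genes(self.genes, outdir / "genes.tsv")
        write_expression(self.expression, outdir / "expr.tsv")
        for mark, by_dialect in self.peaks.items():
            for dialect, records in by_dialect.items():
                write_peaks(records, outdir / f"{mark}.{_DIALECT_EXT[dialect]}", dialect)
        truth = dict(self.truth)
        truth["phi_star"] = self.phi_star.tolist()
        truth["latent_class"] = self.latent_class.tolist()
        truth["spec"] = asdict(self.spec)
        (outdir / "truth.json").write_text(json.dumps(truth, indent=2))


def _make_peak(chrom, start, end, name, signal, rng) -> PeakRecord:
    p = round(float(rng.uniform(2, 30)), 3)
    return PeakRecord(
        chrom=chrom, start=int(start), end=int(end), name=name,
        score=int(min(1000, signal * 100)), strand=".",
        signal_value=round(float(signal), 4), p_value=p, q_value=round(p * 0.8, 3),
        extra={"peak": (end - start) // 2},
    )


def generate_fixture(spec: FixtureSpec) -> SyntheticDataset:
    """Generate one synthetic epigenome under the planted model.

    Deterministic in ``spec.seed``: the same spec yields byte-identical
    files from :meth:`SyntheticDataset.write`.
    """
    rng = np.random.default_rng(spec.seed)
    n, m = spec.n_genes, len(spec.marks)
    half = spec.window // 2
    margin = spec.window
    needed = margin + n * spec.gene_spacing + margin
    chrom_length = spec.chrom_length if spec.chrom_length is not None else needed
    if chrom_length < needed:
        raise ValueError(
            f"chromosome length {chrom_length} too short for {n} non-overlapping "
            f"windows at spacing {spec.gene_spacing}; need >= {needed}"
        )
    jitter_room = spec.gene_spacing - spec.window
    jitter = rng.integers(0, max(jitter_room // 2, 1), size=n)
    tss = margin + half + np.arange(n) * spec.gene_spacing + jitter
    strands = rng.choice(["+", "-"], size=n)
    genes = [
        GeneAnnotation(f"g{i:05d}", spec.chrom, int(tss[i]), str(strands[i]))
        for i in range(n)
    ]

    # planted per-mark enrichments and latent classes
    present = rng.random((n, m)) < np.asarray(spec.peak_rate)
    raw = rng.lognormal(spec.enrich_mu, spec.enrich_sigma, size=(n, m))
    phi_star = np.round(np.where(present, raw, 0.0), 4)
    logit = spec.b_star + phi_star @ np.asarray(spec.w_star)
    prob = expit(logit)
    latent = (rng.random(n) < prob).astype(int)

    # expression from the class-conditional mixture
    flip = rng.random(n) < spec.expr_noise
    eff = np.where(flip, 1 - latent, latent)
    off_draw = rng.exponential(spec.expr_off_scale, size=n)
    on_draw = rng.lognormal(spec.expr_on_mu, spec.expr_on_sigma, size=n)
    expr_vals = np.round(np.where(eff == 1, on_draw, off_draw), 4)
    expression = ExpressionTable({g.gene_id: float(v) for g, v in zip(genes, expr_vals)})

    # materialise peaks: one peak per (gene, mark) with planted enrichment,
    # fully inside the window so max-featurisation recovers phi_star exactly
    lo_len, hi_len = spec.peak_length
    base_peaks: dict[str, list[PeakRecord]] = {mk: [] for mk in spec.marks}
    for i, g in enumerate(genes):
        w_start = g.tss - half
        for j, mk in enumerate(spec.marks):
            if not present[i, j]:
                continue
            length = int(rng.integers(lo_len, hi_len + 1))
            start = w_start + int(rng.integers(0, spec.window - length))
            base_peaks[mk].append(
                _make_peak(spec.chrom, start, start + length,
                           f"{mk}_g{i:05d}", phi_star[i, j], rng)
            )
    # stray background peaks in the gaps between consecutive windows
    for i in range(n - 1):
        gap_lo, gap_hi = int(tss[i]) + half, int(tss[i + 1]) - half
        for j, mk in enumerate(spec.marks):
            if gap_hi - gap_lo <= hi_len + 2 or rng.random() >= spec.background_rate:
                continue
            length = int(rng.integers(lo_len, hi_len + 1))
            start = gap_lo + 1 + int(rng.integers(0, gap_hi - gap_lo - length - 1))
            sig = rng.lognormal(spec.enrich_mu, spec.enrich_sigma)
            base_peaks[mk].append(
                _make_peak(spec.chrom, start, start + length, f"{mk}_bg{i}", sig, rng)
            )

    # all three dialects per mark share the geometry; noise dialects get
    # class-independent signal values
    peaks: dict[str, dict[str, list[PeakRecord]]] = {}
    for mk in spec.marks:
        peaks[mk] = {}
        for dialect in _DIALECT_EXT:
            records = []
            for p in base_peaks[mk]:
                sig = p.signal_value
                if dialect in spec.noise_dialects:
                    sig = round(float(rng.lognormal(spec.enrich_mu, spec.enrich_sigma)), 4)
                records.append(
                    PeakRecord(
                        chrom=p.chrom, start=p.start, end=p.end, name=p.name,
                        score=p.score, strand=p.strand, signal_value=sig,
                        p_value=p.p_value, q_value=p.q_value, extra=dict(p.extra),
                    )
                )
            peaks[mk][dialect] = records

    truth = {
        "w_star": list(spec.w_star),
        "b_star": spec.b_star,
        "phi_star": phi_star,
        "prob": prob.tolist(),
        "latent_class": latent,
    }
    return SyntheticDataset(
        spec=spec, genes=genes, expression=expression, peaks=peaks, truth=truth
    )


def generate_emission_fixture(
    S: int,
    m: int,
    seed: int = 0,
    max_similarity: float = 0.9,
    max_tries: int = 500,
    groups: int | None = None,
):
    """Random emission matrix with pairwise well-separated rows.

    Rows are drawn in (0.02, 0.98)^m and kept only if their mean-centered
    cosine similarity to every already-kept row is at most
    ``max_similarity`` (rejection sampling); raises after ``max_tries``
    failed draws per row. With ``groups`` set, states are assigned round-
    robin to that many group labels.
    """
    from .io import EmissionMatrix

    if S < 2 or m < 2:
        raise ValueError("need at least 2 states and 2 marks")
    rng = np.random.default_rng(seed)
    rows: list[np.ndarray] = []
    while len(rows) < S:
        for attempt in range(max_tries + 1):
            if attempt == max_tries:
                raise RuntimeError(
                    f"could not place {S} emission rows at max pairwise "
                    f"centered-cosine {max_similarity} within {max_tries} tries; "
                    "raise max_similarity or lower S"
                )
            cand = rng.uniform(0.02, 0.98, size=m)
            c = cand - cand.mean()
            nc = np.linalg.norm(c)
            if nc < 0.05:
                continue
            ok = True
            for r in rows:
                rc = r - r.mean()
                if (c @ rc) / (nc * np.linalg.norm(rc)) > max_similarity:
                    ok = False
                    break
            if ok:
                rows.append(cand)
                break
    states = [f"S{i+1}" for i in range(S)]
    grouping = None
    if groups:
        grouping = {s: f"G{(i % groups) + 1}" for i, s in enumerate(states)}
    return EmissionMatrix(
        states=states,
        marks=[f"mark_{j+1}" for j in range(m)],
        E=np.round(np.vstack(rows), 6),
        groups=grouping,
    )


def planted_state_patterns(
    emissions, n_genes: int, noise_sd: float = 0.05, seed: int = 0,
    scale_range: tuple[float, float] = (0.5, 3.0),
):
    """Gene patterns planted as noisy positive-scaled copies of emission rows.

    Returns ``(psi, assignment)``: psi is (n_genes, m) with row g equal to
    ``a * E[assignment[g]] + noise`` for a positive random scale a — so at
    low noise each gene's centered-cosine argmax is its generating state.
    """
    rng = np.random.default_rng(seed)
    S, m = emissions.E.shape
    assignment = rng.integers(0, S, size=n_genes)
    scales = rng.uniform(*scale_range, size=n_genes)
    psi = scales[:, None] * emissions.E[assignment] + rng.normal(0, noise_sd, (n_genes, m))
    return psi, assignment
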