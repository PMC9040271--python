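"""Gene-wise regulative patterns: decomposing predictions by histone mark.

For gene g the weighted input vector is ``psi = phi_g * w`` (element-wise),
and the output logit is ``y = b + sum(psi)``, so sigmoid(y) is exactly the
model's predicted ON probability. Each psi component is the log-odds
contribution of one mark: positive = activator, negative = repressor.
Marks whose Wald test is not significant at alpha (default 1e-4) are masked
grey in displays; for plotting, (psi, b) are jointly rescaled by their max
absolute value so the largest bar is +/-1 while relative signs survive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import expit
from scipy.stats import norm

from .model import GeneStateResults, SeparationError

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 1e-4


@dataclass
class RegulativePattern:
    """Weighted input vector of one gene under one fitted model."""

    gene_id: str
    marks: list[str]
    psi: np.ndarray
    bias: float
    logit: float
    significant: np.ndarray  # per-mark Wald mask at alpha
    alpha: float = DEFAULT_ALPHA

    @property
    def probability(self) -> float:
        """Predicted ON probability reconstructed from the pattern."""
        return float(expit(self.logit))


def significance_test(results: GeneStateResults, alpha: float = DEFAULT_ALPHA) -> dict:
    """Wald Z-tests on the fitted weights: z = w/se, p = 2(1 - Phi_N(|z|)).

    Refuses to run on a separation-flagged fit (its standard errors come
    from a penalised fallback and are not valid Wald inputs).
    """
    if results.separation:
        raise SeparationError("inference refused: fit was separation-flagged")
    se = np.asarray(results.se, dtype=float)
    if np.any(se <= 0) or not np.all(np.isfinite(se)):
        raise SeparationError("degenerate standard errors (se <= 0)")
    z = results.w / se
    p = 2.0 * norm.sf(np.abs(z))
    return {
        "marks": list(results.marks),
        "z": z,
        "p": p,
        "significant": p <= alpha,
        "alpha": float(alpha),
    }


def compute_pattern(
    phi_g: np.ndarray,
    results: GeneStateResults,
    gene_id: str = "",
    alpha: float = DEFAULT_ALPHA,
) -> RegulativePattern:
    """psi = phi_g * w, logit = b + sum(psi), with the Wald mask attached."""
    phi_g = np.asarray(phi_g, dtype=float).ravel()
    if phi_g.shape != results.w.shape:
        raise ValueError(
            f"feature vector length {phi_g.shape[0]} does not match "
            f"{len(results.marks)} model marks"
        )
    psi = phi_g * results.w
    logit = results.b + float(psi.sum())
    try:
        significant = significance_test(results, alpha)["significant"]
    except SeparationError:
        significant = np.zeros(len(psi), dtype=bool)
        logger.warning("pattern for %s built on separation-flagged fit: "
                       "no mark is marked significant", gene_id or "<gene>")
    return RegulativePattern(
        gene_id=gene_id,
        marks=list(results.marks),
        psi=psi,
        bias=results.b,
        logit=logit,
        significant=np.asarray(significant, dtype=bool),
        alpha=alpha,
    )


def normalise_for_display(pattern: RegulativePattern) -> RegulativePattern:
    """Rescale (psi, bias) jointly by their max |.| so the tallest bar is 1.

    Joint scaling keeps the bias bar on a common axis with the mark bars;
    relative magnitudes and all signs are preserved. Idempotent. An
    all-zero pattern with zero bias is returned unchanged with a warning.
    """
    scale = max(float(np.abs(pattern.psi).max(initial=0.0)), abs(pattern.bias))
    if scale == 0.0:
        logger.warning("all-zero pattern for %s: nothing to normalise", pattern.gene_id)
        return pattern
    return RegulativePattern(
        gene_id=pattern.gene_id,
        marks=list(pattern.marks),
        psi=pattern.psi / scale,
        bias=pattern.bias / scale,
        logit=pattern.logit,
        significant=pattern.significant.copy(),
        alpha=pattern.alpha,
    )


def plot_pattern(pattern: RegulativePattern, ax=None, normalise: bool = True):
    """Bar chart of a regulative pattern: green activators, red repressors,
    grey for marks failing the Wald test at alpha; the bias bar is last."""
    import matplotlib.pyplot as plt

    shown = normalise_for_display(pattern) if normalise else pattern
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    values = np.r_[shown.psi, shown.bias]
    labels = list(shown.marks) + ["bias"]
    colors = []
    for j, v in enumerate(values):
        if j < len(shown.psi) and not shown.significant[j]:
            colors.append("0.6")
        else:
            colors.append("forestgreen" if v > 0 else "firebrick")
    ax.bar(range(len(values)), values, color=colors)
    ax.axhline(0.0, color="black", lw=0.8)
    ax.set_xticks(range(len(values)), labels, rotation=45, ha="right")
    ax.set_ylabel("normalised contribution" if normalise else "log-odds contribution")
    ax.set_title(pattern.gene_id or "regulative pattern")
    return ax
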