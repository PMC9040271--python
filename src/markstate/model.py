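"""Logistic modelling of binary gene transcriptional state.

Expression (RPKM) is binarised against a per-sample threshold — by default
the median, so classes are balanced; alternatively a "valley" threshold at
the density minimum between the low/high expression modes. Class OFF is
``t_g <= t_bar`` (ties at the threshold go OFF), ON otherwise.

The classifier is an unpenalised logistic regression on the raw,
unstandardised enrichment features. Keeping the features on their native
scale is deliberate: the interpretation step reads the weighted inputs
``psi = phi * w`` directly against enrichment, and standardisation would
change their meaning. Unpenalised maximum likelihood keeps the Wald
z-tests on coefficients valid; perfect separation triggers a weakly
ridge-penalised fallback whose inference fields are flagged unreliable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field as dc_field
from typing import Mapping, Sequence

import numpy as np
import statsmodels.api as sm
from scipy.stats import gaussian_kde
from sklearn.metrics import average_precision_score, f1_score, roc_auc_score

from .io import ExpressionTable
from .features import FeatureMatrix

logger = logging.getLogger(__name__)

OFF, ON = 0, 1


# ---------------------------------------------------------------------------
# expression thresholds and labels

def median_threshold(expr: Mapping[str, float]) -> float:
    """Per-sample class threshold: the median RPKM.

    With the OFF rule ``t_g <= t_bar`` this yields (near-)balanced classes;
    ties at the median go OFF. A degenerate all-equal table (every gene
    would be OFF) is flagged with a warning.
    """
    if not expr:
        raise ValueError("expression table is empty")
    values = np.asarray(list(expr.values()), dtype=float)
    t_bar = float(np.median(values))
    if np.all(values == values[0]):
        logger.warning(
            "all expression values equal %g: every gene labels OFF", values[0]
        )
    return t_bar


def valley_threshold(
    expr: Mapping[str, float], grid_size: int = 512, bw_method: str | float = "scott"
) -> float:
    """Class threshold at the density valley between expression modes.

    A Gaussian KDE is fitted to log1p(RPKM); the threshold is the density
    minimum between the two highest modes, mapped back to the RPKM scale.
    When the density has no interior local minimum (unimodal data) the
    median is returned with a warning.
    """
    if not expr:
        raise ValueError("expression table is empty")
    values = np.asarray(list(expr.values()), dtype=float)
    logged = np.log1p(values)
    if np.ptp(logged) == 0:
        logger.warning("constant expression: valley undefined, using median")
        return median_threshold(expr)
    kde = gaussian_kde(logged, bw_method=bw_method)
    grid = np.linspace(logged.min(), logged.max(), grid_size)
    dens = kde(grid)
    interior = np.arange(1, grid_size - 1)
    maxima = interior[(dens[interior] > dens[interior - 1]) & (dens[interior] >= dens[interior + 1])]
    # endpoints can carry a mode whose peak sits at the boundary
    if dens[0] > dens[1]:
        maxima = np.r_[0, maxima]
    if dens[-1] > dens[-2]:
        maxima = np.r_[maxima, grid_size - 1]
    if len(maxima) < 2:
        logger.warning("expression density looks unimodal: falling back to median threshold")
        return median_threshold(expr)
    top2 = maxima[np.argsort(dens[maxima])[-2:]]
    lo, hi = int(top2.min()), int(top2.max())
    valley = lo + int(np.argmin(dens[lo : hi + 1]))
    return float(np.expm1(grid[valley]))


@dataclass
class LabelVector:
    """Binary ON/OFF labels for an ordered gene list."""

    gene_ids: list[str]
    T: np.ndarray
    t_bar: float
    rule: str = "median"

    def __post_init__(self) -> None:
        self.T = np.asarray(self.T, dtype=int)
        if set(np.unique(self.T)) - {OFF, ON}:
            raise ValueError("labels must be 0 (OFF) or 1 (ON)")


def binarise(
    expr: Mapping[str, float],
    t_bar: float,
    rule: str = "fixed",
    gene_ids: Sequence[str] | None = None,
) -> LabelVector:
    """Apply the OFF rule ``t_g <= t_bar`` over genes (order preserved)."""
    if t_bar < 0:
        raise ValueError(f"threshold must be nonnegative, got {t_bar}")
    ids = list(gene_ids) if gene_ids is not None else list(expr.keys())
    missing = [g for g in ids if g not in expr]
    if missing:
        raise KeyError(f"genes absent from expression table: {missing[:5]}")
    T = np.array([OFF if expr[g] <= t_bar else ON for g in ids], dtype=int)
    return LabelVector(gene_ids=ids, T=T, t_bar=float(t_bar), rule=rule)


def label_expression(expr: Mapping[str, float], rule: str = "median",
                     gene_ids: Sequence[str] | None = None) -> LabelVector:
    """Threshold-and-binarise in one step (rule: median | valley)."""
    if rule == "median":
        t_bar = median_threshold(expr)
    elif rule == "valley":
        t_bar = valley_threshold(expr)
    else:
        raise ValueError(f"unknown threshold rule {rule!r}")
    return binarise(expr, t_bar, rule=rule, gene_ids=gene_ids)


# ---------------------------------------------------------------------------
# the model / results pair

class SeparationError(RuntimeError):
    """Raised when coefficient inference is requested on a separation-flagged fit."""


class GeneStateLogit:
    """Logistic regression of gene ON/OFF state on per-mark peak enrichment.

    Parameters
    ----------
    Phi : (n, m) nonnegative feature matrix (genes x marks)
    T : (n,) binary labels, 1 = ON
    marks : mark names (length m); default mark_1..mark_m
    gene_ids : optional gene identifiers (length n)

    Examples
    --------
    >>> model = GeneStateLogit(Phi, T, marks=list("abcde"))
    >>> res = model.fit()
    >>> res.params, res.pvalues
    """

    def __init__(
        self,
        Phi: np.ndarray,
        T: np.ndarray,
        marks: Sequence[str] | None = None,
        gene_ids: Sequence[str] | None = None,
    ):
        self.Phi = np.asarray(Phi, dtype=float)
        if self.Phi.ndim != 2:
            raise ValueError("Phi must be 2-D (genes x marks)")
        self.T = np.asarray(T, dtype=int)
        n, m = self.Phi.shape
        if self.T.shape != (n,):
            raise ValueError(f"labels shape {self.T.shape} does not match {n} genes")
        classes, counts = np.unique(self.T, return_counts=True)
        if len(classes) < 2:
            raise ValueError("training labels contain a single class")
        if counts.min() < 2:
            raise ValueError("need at least 2 samples per class")
        self.marks = list(marks) if marks is not None else [f"mark_{j+1}" for j in range(m)]
        if len(self.marks) != m:
            raise ValueError("marks length does not match Phi columns")
        self.gene_ids = list(gene_ids) if gene_ids is not None else None

    @classmethod
    def from_features(
        cls,
        features: FeatureMatrix,
        expression: Mapping[str, float],
        threshold: str = "median",
    ) -> "GeneStateLogit":
        """Assemble the dataset D = <Phi, T> from a feature matrix and an
        expression table, binarising with the given threshold rule."""
        labels = label_expression(expression, rule=threshold, gene_ids=features.gene_ids)
        model = cls(features.Phi, labels.T, marks=features.marks, gene_ids=features.gene_ids)
        model.labels = labels
        return model

    def fit(self, ridge_on_separation: bool = True, maxiter: int = 200) -> "GeneStateResults":
        """Unpenalised MLE fit with intercept; Wald inference per mark.

        On perfect separation (or a non-converged / singular fit) the model
        refits with a weak L2 penalty so predictions remain usable, and the
        results are flagged: standard errors and p-values are then NaN and
        ``significance_test`` refuses to run.
        """
        X = sm.add_constant(self.Phi, has_constant="add")
        separation = False
        res = None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = sm.Logit(self.T, X).fit(disp=0, maxiter=maxiter)
                bad = (
                    not res.mle_retvals.get("converged", False)
                    or not np.all(np.isfinite(res.bse))
                    or np.abs(res.params).max() > 1e3
                )
                if bad:
                    separation = True
            except Exception:  # PerfectSeparationError or singular Hessian
                separation = True
        if separation:
            if not ridge_on_separation:
                raise SeparationError("perfect separation and ridge fallback disabled")
            logger.warning(
                "separation or non-convergence detected: refitting with a weak "
                "ridge penalty; coefficient inference is unreliable"
            )
            from sklearn.linear_model import LogisticRegression

            clf = LogisticRegression(C=100.0, max_iter=2000)
            clf.fit(self.Phi, self.T)
            w = clf.coef_.ravel().astype(float)
            b = float(clf.intercept_[0])
            se = np.full(len(w), np.nan)
            return GeneStateResults(
                model=self, w=w, b=b, se=se, se_b=np.nan,
                converged=True, separation=True,
            )
        params = np.asarray(res.params, dtype=float)
        bse = np.asarray(res.bse, dtype=float)
        return GeneStateResults(
            model=self,
            w=params[1:],
            b=float(params[0]),
            se=bse[1:],
            se_b=float(bse[0]),
            converged=bool(res.mle_retvals.get("converged", False)),
            separation=False,
            llf=float(res.llf),
        )


@dataclass
class GeneStateResults:
    """Fitted logistic gene-state model: weights, bias and Wald inference.

    ``w[j]`` is the log-odds change of the ON state per unit enrichment of
    mark j; a negative weight marks a repressor, a positive one an
    activator. ``b`` is the bias — the prior log-odds of activation for a
    gene with no measured peaks.
    """

    model: GeneStateLogit
    w: np.ndarray
    b: float
    se: np.ndarray
    se_b: float
    converged: bool = True
    separation: bool = False
    llf: float = np.nan
    hyperparameters: dict = dc_field(default_factory=dict)

    @property
    def marks(self) -> list[str]:
        return self.model.marks

    @property
    def params(self) -> np.ndarray:
        """(b, w_1..w_m) in statsmodels order (intercept first)."""
        return np.r_[self.b, self.w]

    @property
    def bse(self) -> np.ndarray:
        return np.r_[self.se_b, self.se]

    @property
    def zvalues(self) -> np.ndarray:
        if self.separation:
            raise SeparationError(
                "fit was separation-flagged: Wald statistics are unavailable"
            )
        if np.any(self.se <= 0):
            raise SeparationError("degenerate standard error (se <= 0)")
        return self.w / self.se

    @property
    def pvalues(self) -> np.ndarray:
        """Two-sided Wald p-values per mark (excluding the bias)."""
        from scipy.stats import norm

        return 2.0 * norm.sf(np.abs(self.zvalues))

    def logits(self, Phi: np.ndarray) -> np.ndarray:
        Phi = np.asarray(Phi, dtype=float)
        return self.b + Phi @ self.w

    def predict(self, Phi: np.ndarray) -> np.ndarray:
        """Predicted probability of the ON state."""
        from scipy.special import expit

        return expit(self.logits(Phi))

    def evaluate(self, Phi_test: np.ndarray, T_test: np.ndarray) -> dict[str, float]:
        return evaluate(self, Phi_test, T_test)

    def regulative_pattern(self, phi_g: np.ndarray, gene_id: str = "",
                           alpha: float = 1e-4):
        from .interpret import compute_pattern

        return compute_pattern(phi_g, self, gene_id=gene_id, alpha=alpha)

    def summary(self) -> str:
        """Plain-text coefficient table in the statsmodels idiom."""
        lines = [
            "Gene-state logistic regression",
            f"  n = {len(self.model.T)}, marks = {len(self.marks)}, "
            f"converged = {self.converged}, separation = {self.separation}",
            f"  {'term':<12}{'coef':>10}{'std err':>10}{'z':>9}{'P>|z|':>10}",
        ]
        if self.separation:
            rows = [("bias", self.b, np.nan, np.nan, np.nan)] + [
                (m, wj, np.nan, np.nan, np.nan) for m, wj in zip(self.marks, self.w)
            ]
        else:
            z, p = self.zvalues, self.pvalues
            zb = self.b / self.se_b if self.se_b > 0 else np.nan
            from scipy.stats import norm

            pb = 2.0 * norm.sf(abs(zb)) if np.isfinite(zb) else np.nan
            rows = [("bias", self.b, self.se_b, zb, pb)] + [
                (m, wj, sj, zj, pj)
                for m, wj, sj, zj, pj in zip(self.marks, self.w, self.se, z, p)
            ]
        for term, coef, se, z_, p_ in rows:
            lines.append(f"  {term:<12}{coef:>10.4f}{se:>10.4f}{z_:>9.3f}{p_:>10.2g}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "marks": list(self.marks),
            "w": self.w.tolist(),
            "b": self.b,
            "se": [None if not np.isfinite(s) else s for s in np.atleast_1d(self.se)],
            "se_b": None if not np.isfinite(self.se_b) else self.se_b,
            "converged": self.converged,
            "separation": self.separation,
            "hyperparameters": dict(self.hyperparameters),
        }


def fit_logistic(
    Phi_train: np.ndarray,
    T_train: np.ndarray,
    marks: Sequence[str] | None = None,
) -> GeneStateResults:
    """Convenience wrapper: build :class:`GeneStateLogit` and fit it."""
    return GeneStateLogit(Phi_train, T_train, marks=marks).fit()


# ---------------------------------------------------------------------------
# evaluation

def evaluate(results: GeneStateResults, Phi_test: np.ndarray, T_test: np.ndarray) -> dict[str, float]:
    """Test metrics: AUROC (midrank ties), F1 at probability 0.5 with ON
    positive, and AUPR by precision-recall step integration.

    Single-class test labels leave AUROC/AUPR undefined: they are reported
    as NaN with a warning, F1 is still computed.
    """
    T_test = np.asarray(T_test, dtype=int)
    scores = results.predict(Phi_test)
    out: dict[str, float] = {}
    if len(np.unique(T_test)) < 2:
        logger.warning("single-class test labels: AUROC and AUPR undefined")
        out["auroc"] = np.nan
        out["aupr"] = np.nan
    else:
        out["auroc"] = float(roc_auc_score(T_test, scores))
        out["aupr"] = float(average_precision_score(T_test, scores))
    out["f1"] = float(f1_score(T_test, (scores > 0.5).astype(int), pos_label=ON, zero_division=0))
    return out
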