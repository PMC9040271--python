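"""Experiment orchestration: splits, peak-format selection, repeated runs.

The evaluation protocol fits on a random third of the genes, selects the
per-mark peak format (narrow / broad / gapped) on a validation third by
AUROC, and scores the test third; the whole procedure is repeated over k
independent random splits and summarised as mean +/- sd.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field as dc_field
from typing import Mapping, Sequence

import numpy as np

from .features import FeatureMatrix
from .model import GeneStateLogit, GeneStateResults, evaluate

logger = logging.getLogger(__name__)

#: preference order used to break validation-AUROC ties
DIALECT_PREFERENCE = ("narrow", "broad", "gapped")


@dataclass(frozen=True)
class DatasetSplit:
    """Disjoint, exhaustive train/validation/test gene index sets."""

    train_idx: np.ndarray
    val_idx: np.ndarray
    test_idx: np.ndarray
    seed: int

    @property
    def sizes(self) -> tuple[int, int, int]:
        return len(self.train_idx), len(self.val_idx), len(self.test_idx)


def split_dataset(n: int, seed: int) -> DatasetSplit:
    """Random ceil-balanced thirds: train = ceil(n/3), then validation takes
    the ceiling of what remains, test the rest (19802 -> 6601/6601/6600)."""
    if n < 3:
        raise ValueError(f"need at least 3 genes to split, got {n}")
    n_train = math.ceil(n / 3)
    n_val = math.ceil((n - n_train) / 2)
    perm = np.random.default_rng(seed).permutation(n)
    return DatasetSplit(
        train_idx=perm[:n_train],
        val_idx=perm[n_train : n_train + n_val],
        test_idx=perm[n_train + n_val :],
        seed=seed,
    )


# ---------------------------------------------------------------------------
# per-mark peak-format (dialect) selection

def _tie_key(config: Mapping[str, str], marks: Sequence[str]) -> tuple:
    def rank(d: str) -> int:
        return DIALECT_PREFERENCE.index(d) if d in DIALECT_PREFERENCE else len(DIALECT_PREFERENCE)

    return tuple((rank(config[m]), config[m]) for m in marks)


def _assemble(features: Mapping[str, Mapping[str, np.ndarray]],
              config: Mapping[str, str], marks: Sequence[str]) -> np.ndarray:
    return np.column_stack([features[m][config[m]] for m in marks])


def _fit_and_score(Phi: np.ndarray, T: np.ndarray, marks: Sequence[str],
                   train_idx: np.ndarray, val_idx: np.ndarray) -> tuple[GeneStateResults, float]:
    res = GeneStateLogit(Phi[train_idx], T[train_idx], marks=marks).fit()
    metrics = evaluate(res, Phi[val_idx], T[val_idx])
    return res, metrics["auroc"]


def select_hyperparameters(
    features: Mapping[str, Mapping[str, np.ndarray]],
    T: np.ndarray,
    train_idx: np.ndarray,
    val_idx: np.ndarray,
    marks: Sequence[str] | None = None,
    search: str = "exhaustive",
) -> tuple[dict[str, str], GeneStateResults, float, int]:
    """Choose one peak format per mark by validation AUROC.

    Parameters
    ----------
    features : mark -> {dialect -> feature column over all genes}
    T : binary labels over all genes
    search : "exhaustive" over the Cartesian product of per-mark dialects,
        or "greedy" (one mark at a time against the preference-order
        baseline) when the product is large

    Returns ``(H, results, val_auroc, n_evaluated)`` where ``H`` maps each
    mark to its chosen dialect and ``results`` is the model refitted on the
    training set under ``H``. Ties break by dialect preference
    (narrow > broad > gapped), then lexicographically.
    """
    marks = list(marks) if marks is not None else list(features)
    for m in marks:
        if not features.get(m):
            raise ValueError(f"no candidate dialect for mark {m!r}")
    candidates = {
        m: sorted(features[m], key=lambda d: _tie_key({m: d}, [m])) for m in marks
    }
    n_eval = 0

    def score(config: dict[str, str]) -> tuple[GeneStateResults, float]:
        nonlocal n_eval
        n_eval += 1
        return _fit_and_score(_assemble(features, config, marks), np.asarray(T, dtype=int),
                              marks, train_idx, val_idx)

    if search == "exhaustive":
        best = None
        for combo in itertools.product(*(candidates[m] for m in marks)):
            config = dict(zip(marks, combo))
            res, auroc = score(config)
            key = (-auroc, _tie_key(config, marks))
            if best is None or key < best[0]:
                best = (key, config, res, auroc)
        _, config, res, auroc = best
    elif search == "greedy":
        config = {m: candidates[m][0] for m in marks}
        res, auroc = score(config)
        for m in marks:
            for d in candidates[m]:
                if d == config[m]:
                    continue
                trial = dict(config, **{m: d})
                r2, a2 = score(trial)
                if a2 > auroc:
                    config, res, auroc = trial, r2, a2
    else:
        raise ValueError(f"unknown search mode {search!r}")
    res.hyperparameters = dict(config)
    return dict(config), res, float(auroc), n_eval


# ---------------------------------------------------------------------------
# repeated-split experiment

@dataclass
class EvalReport:
    """Per-split test metrics and their mean/sd over k repeated splits."""

    splits: list[dict] = dc_field(default_factory=list)

    @property
    def k(self) -> int:
        return len(self.splits)

    def metric(self, name: str) -> np.ndarray:
        return np.array([s["metrics"][name] for s in self.splits], dtype=float)

    def mean(self, name: str) -> float:
        return float(np.nanmean(self.metric(name)))

    def sd(self, name: str) -> float:
        vals = self.metric(name)
        return float(np.nanstd(vals, ddof=1)) if len(vals) > 1 else 0.0

    def summary(self) -> str:
        lines = [f"Repeated-split evaluation (k = {self.k})"]
        for name in ("auroc", "f1", "aupr"):
            lines.append(f"  test {name.upper():<6} {self.mean(name):.4f} +/- {self.sd(name):.4f}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "splits": [
                {
                    "seed": s["seed"],
                    "metrics": s["metrics"],
                    "hyperparameters": s.get("hyperparameters"),
                }
                for s in self.splits
            ],
            "mean": {m: self.mean(m) for m in ("auroc", "f1", "aupr")},
            "sd": {m: self.sd(m) for m in ("auroc", "f1", "aupr")},
        }


def _split_seeds(master_seed: int, k: int) -> list[int]:
    """Expand one master seed into k split seeds deterministically."""
    rng = np.random.default_rng(master_seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=k)]


def run_experiment(
    features: FeatureMatrix | Mapping[str, Mapping[str, np.ndarray]],
    T: np.ndarray,
    k: int = 10,
    seed: int = 0,
    marks: Sequence[str] | None = None,
    search: str = "exhaustive",
) -> EvalReport:
    """Tune and evaluate over k independent random splits.

    ``features`` is either a single :class:`FeatureMatrix` (no tuning: the
    model is fitted on train and scored on test) or a mark -> dialect ->
    column mapping, in which case the peak format per mark is selected on
    validation AUROC within each split. Fully reproducible from ``seed``.
    """
    T = np.asarray(T, dtype=int)
    n = len(T)
    report = EvalReport()
    tuned = not isinstance(features, FeatureMatrix)
    if not tuned and marks is None:
        marks = features.marks
    for split_seed in _split_seeds(seed, k):
        split = split_dataset(n, split_seed)
        if tuned:
            H, res, _, _ = select_hyperparameters(
                features, T, split.train_idx, split.val_idx, marks=marks, search=search
            )
            Phi = _assemble(features, H, res.marks)
        else:
            H = dict(features.dialects or {})
            Phi = features.Phi
            res = GeneStateLogit(Phi[split.train_idx], T[split.train_idx], marks=marks).fit()
            res.hyperparameters = H
        metrics = evaluate(res, Phi[split.test_idx], T[split.test_idx])
        report.splits.append(
            {"seed": split_seed, "metrics": metrics, "hyperparameters": H, "results": res}
        )
    if k == 1:
        logger.info("k=1: standard deviation reported as 0")
    return report
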