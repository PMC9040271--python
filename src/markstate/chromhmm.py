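"""Matching regulative patterns against ChromHMM emission vectors.

Each test gene's regulative pattern is matched to the chromatin state
whose emission vector maximises the Pearson correlation with it —
equivalently the cosine similarity of the two mean-centered vectors. The
matched genes' output logits are then pooled per state (or per coarser
state group) and averaged, and states/groups are ranked by mean logit:
rank 1 should land on actively transcribed chromatin if the model's
patterns carry the right semantics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .interpret import RegulativePattern
from .io import EmissionMatrix, ValidationError

logger = logging.getLogger(__name__)


def default_state_groups() -> dict[str, str]:
    """Reconstructed 4-group clustering of the REMC 15-state mnemonics
    (Active / Enhancers / Bivalent / Repressed); user-overridable."""
    path = resources.files("markstate.data").joinpath("remc15_groups.tsv")
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["state"], df["group"]))


def pattern_state_correlation(psi: np.ndarray, emission_row: np.ndarray) -> float:
    """Pearson correlation as centered cosine similarity.

    A constant vector has zero centered norm; its correlation is defined
    as 0 with a warning (such genes carry no pattern to match).
    """
    a = np.asarray(psi, dtype=float).ravel()
    b = np.asarray(emission_row, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape[0]} vs {b.shape[0]}")
    ac = a - a.mean()
    bc = b - b.mean()
    na, nb = np.linalg.norm(ac), np.linalg.norm(bc)
    if na == 0.0 or nb == 0.0:
        logger.warning("constant vector in correlation: defined as 0")
        return 0.0
    return float(ac @ bc / (na * nb))


@dataclass(frozen=True)
class StateMatch:
    """One gene matched to its most-correlated chromatin state."""

    gene_id: str
    state: str
    correlation: float
    matched: bool = True  # False for zero-pattern genes (tie-break only)


def match_states(
    patterns: Sequence[RegulativePattern], emissions: EmissionMatrix
) -> list[StateMatch]:
    """Match each pattern to the argmax-correlation state.

    Emission mark columns are realigned to the pattern mark order by name;
    ties break to the lowest state index. Genes with an identically-zero
    pattern (no peaks at all) correlate 0 with every state: they receive
    the tie-break state but are flagged ``matched=False`` so gathering can
    exclude them.
    """
    if not patterns:
        raise ValueError("no patterns to match")
    marks = patterns[0].marks
    E = emissions.reorder_marks(marks) if emissions.marks != marks else emissions
    # centered, normalised emission rows; constant rows get zero vectors
    Ec = E.E - E.E.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Ec, axis=1)
    safe = np.where(norms > 0, norms, 1.0)
    Ec = Ec / safe[:, None]
    Ec[norms == 0] = 0.0
    out = []
    for pat in patterns:
        if pat.marks != marks:
            raise ValidationError(f"pattern mark order differs for {pat.gene_id}")
        v = pat.psi - pat.psi.mean()
        nv = np.linalg.norm(v)
        if nv == 0.0:
            out.append(StateMatch(pat.gene_id, E.states[0], 0.0, matched=False))
            continue
        corr = Ec @ (v / nv)
        best = int(np.argmax(corr))  # argmax takes the lowest index on ties
        out.append(StateMatch(pat.gene_id, E.states[best], float(corr[best])))
    return out


@dataclass
class RankTable:
    """States or groups ranked by the mean output logit of matched genes."""

    level: str  # "state" | "group"
    table: pd.DataFrame  # columns: label, mean_logit, n_genes, rank

    def rank_of(self, label: str) -> int:
        row = self.table[self.table["label"] == label]
        if row.empty:
            raise KeyError(label)
        return int(row["rank"].iloc[0])

    @property
    def labels_by_rank(self) -> list[str]:
        return list(self.table.sort_values("rank")["label"])


def gather_and_rank(
    matches: Sequence[StateMatch],
    patterns: Sequence[RegulativePattern],
    grouping: Mapping[str, str] | None = None,
    include_unmatched: bool = False,
    labels: Sequence[str] | None = None,
) -> RankTable:
    """Pool matched genes' logits per state (or group) and rank by mean.

    With ``grouping`` the genes are pooled by their matched state's group
    and the rank is computed at that coarser level directly (not averaged
    from state ranks). States/groups with no matched genes are reported
    with a missing mean and excluded from ranking. Rank 1 = highest mean
    logit. ``labels`` names the full label universe (e.g. all emission
    states) so empty ones can be reported; it defaults to the grouping's
    group set at group level, or to the observed states otherwise.
    """
    logit_by_gene = {p.gene_id: p.logit for p in patterns}
    level = "group" if grouping is not None else "state"
    pooled: dict[str, list[float]] = {}
    for m in matches:
        if not m.matched and not include_unmatched:
            continue
        if grouping is not None:
            if m.state not in grouping:
                raise ValidationError(f"state {m.state!r} missing from grouping")
            label = grouping[m.state]
        else:
            label = m.state
        pooled.setdefault(label, []).append(logit_by_gene[m.gene_id])
    observed = sorted(pooled)
    if labels is not None:
        all_labels = list(labels)
    elif grouping is not None:
        all_labels = sorted(set(grouping.values()))
    else:
        all_labels = observed
    empty = [lab for lab in all_labels if lab not in pooled]
    if empty:
        logger.info("no matched genes for %s(s) %s: excluded from ranking", level, empty)
    rows = [
        {"label": lab, "mean_logit": float(np.mean(pooled[lab])), "n_genes": len(pooled[lab])}
        for lab in observed
    ]
    df = pd.DataFrame(rows).sort_values("mean_logit", ascending=False, kind="stable")
    df["rank"] = np.arange(1, len(df) + 1)
    for lab in empty:
        df = pd.concat(
            [df, pd.DataFrame([{"label": lab, "mean_logit": np.nan, "n_genes": 0, "rank": pd.NA}])],
            ignore_index=True,
        )
    return RankTable(level=level, table=df.reset_index(drop=True))


def rank_histogram(rank_tables: Sequence[RankTable]) -> pd.DataFrame:
    """Count, per group label, how often each rank occurs across epigenomes.

    Rows are labels, columns rank values; entry (g, r) = number of input
    tables in which label g attained rank r.
    """
    if not rank_tables:
        raise ValueError("no rank tables given")
    label_sets = [frozenset(t.table["label"]) for t in rank_tables]
    if len(set(label_sets)) != 1:
        raise ValidationError("rank tables do not share one label set")
    labels = sorted(label_sets[0])
    max_rank = len(labels)
    counts = pd.DataFrame(0, index=labels, columns=range(1, max_rank + 1))
    for t in rank_tables:
        for _, row in t.table.iterrows():
            if pd.notna(row["rank"]):
                counts.loc[row["label"], int(row["rank"])] += 1
    counts.index.name = "label"
    return counts
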