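import numpy as np
import pytest

from markstate import FixtureSpec, generate_fixture, label_expression


@pytest.fixture(scope="session")
def small_dataset():
    """A modest synthetic epigenome shared across read-only tests."""
    return generate_fixture(FixtureSpec(n_genes=600, seed=101))


@pytest.fixture(scope="session")
def small_features(small_dataset):
    return small_dataset.featurise("narrow")


@pytest.fixture(scope="session")
def small_labels(small_dataset, small_features):
    return label_expression(
        small_dataset.expression, gene_ids=small_features.gene_ids
    )


@pytest.fixture(scope="session")
def fitted(small_features, small_labels):
    from markstate import GeneStateLogit

    return GeneStateLogit(
        small_features.Phi, small_labels.T, marks=small_features.marks
    ).fit()


def brute_force_auroc(scores, labels) -> float:
    """All-pairs concordance oracle: fraction of (ON, OFF) pairs where the
    ON gene scores higher, ties counted half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def naive_feature_value(peaks, field, aggregator="max"):
    """Per-position membership oracle: materialise the full length-l vector
    by scanning genomic positions, then collapse it."""
    # genomic coordinates of every vector position (negative when clipped:
    # those can never be covered by a peak, so they stay zero)
    positions = np.arange(field.end - field.length, field.end)
    x = np.zeros(field.length, dtype=float)
    n_over = 0
    for p in peaks:
        if p.chrom != field.chrom:
            continue
        mask = (positions >= p.start) & (positions < p.end)
        if mask.any():
            n_over += 1
            x = np.maximum(x, np.where(mask, p.signal_value, 0.0))
    if aggregator == "max":
        return x.max(initial=0.0)
    if aggregator == "sum":
        return x.sum()
    if aggregator == "mean":
        return x.mean()
    if aggregator == "count":
        return float(n_over)
    raise ValueError(aggregator)
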