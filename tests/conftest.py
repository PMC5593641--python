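import numpy as np
import pytest

import celldx as cx


@pytest.fixture(scope="session")
def cohort_table():
    """Study-like synthetic cohort: 5 patients x 2 phases x 400 cells."""
    cfg = cx.default_cohort_config(cells_per_specimen=400, seed=123)
    return cx.generate_cohort(cfg)


@pytest.fixture(scope="session")
def log_table(cohort_table):
    return cx.log_transform(cohort_table)


@pytest.fixture(scope="session")
def dev_val(log_table):
    return cx.split_development_validation(
        log_table, ["P1", "P2", "P3"], ["P4", "P5"]
    )


@pytest.fixture(scope="session")
def epithelial_fit(dev_val):
    dev, _ = dev_val
    return cx.fit_logistic(cx.filter_compartment(dev, ["E"]))


def brute_force_knn_labels(query, reference, labels, cov_inv, k):
    """Exhaustive-distance k-NN oracle with the same tie conventions."""
    out = []
    for x0 in query:
        d = np.array([cx.mahalanobis_distance(x0, r, cov_inv) for r in reference])
        nn = np.argsort(d, kind="stable")[:k]
        classes, counts = np.unique(labels[nn], return_counts=True)
        top = counts.max()
        winners = classes[counts == top]
        out.append(cx.ABSTAIN if len(winners) > 1 else winners[0])
    return np.asarray(out, dtype=object)


def pairwise_concordance_auc(scores, truth):
    """O(n^2) AUC oracle: concordant pairs, ties counted 1/2."""
    scores = np.asarray(scores, float)
    truth = np.asarray(truth, bool)
    pos = scores[truth]
    neg = scores[~truth]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))
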