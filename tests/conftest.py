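"""Shared fixtures and the naive scalar oracle for the fusion rule.

The oracle transcribes the fusion arithmetic sample-by-sample,
class-by-class, classifier-by-classifier with plain Python floats — no
numpy vectorization — so it stays independent of the implementation path
it checks.
"""

import math

import numpy as np
import pytest

from rankfuse.fusion_core import EnsembleScoreSet


def scalar_rank(x: float) -> float:
    """Scalar transcription of the Mitscherlich rank transform."""
    return 2.0 * (1.0 - 2.0 ** (x - 1.0))


def scalar_fuse(matrices, k, variant="complement"):
    """Naive per-sample/class/classifier transcription of the fusion rule.

    ``matrices``: list of M lists of rows (each row a list of C
    confidences, assumed normalized). Returns (frs, ccfs, fds,
    fused_index) as nested lists / list of ints.
    """
    m = len(matrices)
    n = len(matrices[0])
    c = len(matrices[0][0])
    frs_all, ccfs_all, fds_all, fused = [], [], [], []
    for s in range(n):
        # per-classifier top-k membership via ordinal ranks
        memberships = []
        for i in range(m):
            ranks = [scalar_rank(matrices[i][s][j]) for j in range(c)]
            order = sorted(range(c), key=lambda j: (ranks[j], j))
            memberships.append(set(order[:k]))
        frs_row, ccfs_row, fds_row = [], [], []
        for j in range(c):
            frs = 0.0
            conf_sum = 0.0
            for i in range(m):
                if j in memberships[i]:
                    frs += scalar_rank(matrices[i][s][j])
                    conf_sum += matrices[i][s][j]
                else:
                    frs += 1.0   # rank penalty
                    conf_sum += 0.0  # confidence penalty
            mean_conf = conf_sum / m
            ccfs = mean_conf if variant == "literal" else 1.0 - mean_conf
            frs_row.append(frs)
            ccfs_row.append(ccfs)
            fds_row.append(frs * ccfs)
        best = min(range(c), key=lambda j: (fds_row[j], j))
        frs_all.append(frs_row)
        ccfs_all.append(ccfs_row)
        fds_all.append(fds_row)
        fused.append(best)
    return frs_all, ccfs_all, fds_all, fused


def random_bank(rng, n, c, m, class_labels=None) -> EnsembleScoreSet:
    """Random row-stochastic score set (Dirichlet rows)."""
    scores = rng.dirichlet(np.ones(c), size=(m, n))
    return EnsembleScoreSet(
        scores=scores,
        sample_ids=[f"s{j}" for j in range(n)],
        class_labels=class_labels or [f"c{j + 1}" for j in range(c)],
    )


@pytest.fixture
def worked_bank() -> EnsembleScoreSet:
    """Three models, one sample: two favour class 1, one favours class 2."""
    scores = np.array(
        [
            [[0.7, 0.2, 0.1]],
            [[0.6, 0.3, 0.1]],
            [[0.1, 0.8, 0.1]],
        ]
    )
    return EnsembleScoreSet(
        scores=scores, sample_ids=["s1"], class_labels=["c1", "c2", "c3"]
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240311)
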