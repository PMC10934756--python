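"""Shared fixtures and independent brute-force oracles.

The oracle callables here are deliberately naive re-derivations (loops,
exhaustive enumeration, dense sampling) kept separate from the production
code paths they check.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from drowsikit import synth
from drowsikit.eye_state import EyeImage


def split_corpus(corpus, n_train_per_class=70):
    """First n_train per class to training, rest to test (class-alternating
    corpus order keeps both halves balanced)."""
    seen: dict = {}
    train, test = [], []
    for img in corpus:
        k = seen.setdefault(img.label, 0)
        (train if k < n_train_per_class else test).append(img)
        seen[img.label] = k + 1
    return train, test


@pytest.fixture(scope="session")
def eye_corpus():
    """The 200-image synthetic corpus (100 per class) at one fixed seed."""
    return synth.gen_eye_corpus(100, seed=0)


@pytest.fixture(scope="session")
def corpus_split(eye_corpus):
    return split_corpus(eye_corpus)


@pytest.fixture(scope="session")
def trained_mlp(corpus_split):
    from drowsikit.eye_state import train_mlp

    return train_mlp(corpus_split[0], seed=0)


# ---------------------------------------------------------------------------
# Oracles


def segment_oracle(values, threshold):
    """Frame-by-frame enumeration of maximal sub-threshold runs."""
    intervals, start = [], None
    for i, v in enumerate(values):
        if v < threshold:
            if start is None:
                start = i
        else:
            if start is not None:
                intervals.append((start, i))
                start = None
    if start is not None:
        intervals.append((start, len(values)))
    return intervals


@pytest.fixture
def segmentation_oracle():
    return segment_oracle


def mamdani_dense_oracle(scores, input_mfs, output_mfs, rules, n=1001):
    """Direct pointwise Mamdani evaluation on a dense output grid.

    Trapezoids are evaluated with scalar arithmetic, rules with explicit
    loops, the centroid with plain Riemann sums — independent of the
    vectorised production engine.
    """

    def trap(x, mf):
        if x <= mf.a or x >= mf.d:
            # plateau endpoints still count as membership 1
            if mf.a == mf.b and x == mf.a:
                return 1.0
            if mf.c == mf.d and x == mf.d:
                return 1.0
            return 0.0
        if x < mf.b:
            return (x - mf.a) / (mf.b - mf.a)
        if x <= mf.c:
            return 1.0
        return (mf.d - x) / (mf.d - mf.c)

    zs = [i / (n - 1) for i in range(n)]
    agg = [0.0] * n
    for rule in rules:
        strength = min(
            trap(s, input_mfs[t]) for s, t in zip(scores, rule.antecedent)
        )
        mf = output_mfs[rule.consequent]
        for i, z in enumerate(zs):
            agg[i] = max(agg[i], min(strength, trap(z, mf)))
    num = sum(a * z for a, z in zip(agg, zs))
    den = sum(agg)
    if den == 0:
        raise ValueError("no rule fired")
    return num / den


@pytest.fixture
def mamdani_oracle():
    return mamdani_dense_oracle


def max_disjoint_triples(t1, t2, t3, tol):
    """Maximum number of pairwise-coincident, pulse-disjoint (EOG1, EOG2,
    EOG3) triples, by exhaustive search.  Times are per-channel lists of
    correctly-typed pulse times."""
    triples = [
        (i, j, k)
        for i, j, k in itertools.product(range(len(t1)), range(len(t2)), range(len(t3)))
        if abs(t1[i] - t2[j]) <= tol
        and abs(t1[i] - t3[k]) <= tol
        and abs(t2[j] - t3[k]) <= tol
    ]

    best = 0

    def recurse(chosen, remaining):
        nonlocal best
        best = max(best, len(chosen))
        for idx, tri in enumerate(remaining):
            used = set()
            for c in chosen:
                used |= {("a", c[0]), ("b", c[1]), ("c", c[2])}
            if {("a", tri[0]), ("b", tri[1]), ("c", tri[2])} & used:
                continue
            recurse(chosen + [tri], remaining[idx + 1 :])

    recurse([], triples)
    return best


@pytest.fixture
def triple_matching_oracle():
    return max_disjoint_triples


def make_eye_image(value=0.5, shape=(51, 51), label=None):
    return EyeImage(np.full(shape, float(value)), label=label)
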