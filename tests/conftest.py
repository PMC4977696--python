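"""Shared fixtures and independent oracles.

The oracles here are deliberately naive re-implementations (full-matrix
Gotoh DP, per-column set-logic classification) kept free of any code from
the package's alignment path, so that implementation and oracle can only
agree by being right.
"""

from __future__ import annotations

import numpy as np
import pytest

from clusterscope._iupac import AMBIGUITY_CODES, IUPAC_SETS

BASES = "ACGT"
NEG = float("-inf")


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, n))


def random_protein(rng: np.random.Generator, n: int) -> str:
    aas = "ACDEFGHIKLMNPQRSTVWY"
    return "".join(aas[i] for i in rng.integers(0, len(aas), n))


def gotoh_score(a: str, b: str, sub, gap_open: float, gap_extend: float) -> float:
    """Optimal global affine-gap score by full-matrix DP.

    Gap of length L costs ``gap_open + (L - 1) * gap_extend``; end gaps are
    penalized (true global alignment).
    """
    n, m = len(a), len(b)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = gap_open + (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0][j] = gap_open + (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = sub(a[i - 1], b[j - 1])
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] + gap_open, X[i - 1][j] + gap_extend,
                          Y[i - 1][j] + gap_open)
            Y[i][j] = max(M[i][j - 1] + gap_open, Y[i][j - 1] + gap_extend,
                          X[i][j - 1] + gap_open)
    return max(M[n][m], X[n][m], Y[n][m])


def classify_oracle(a_gapped: str, b_gapped: str) -> dict[str, int]:
    """Column classes by direct set logic, one column at a time."""
    counts = {"match": 0, "genuine_substitution": 0, "gap": 0, "ambiguity": 0}
    for x, y in zip(a_gapped, b_gapped):
        if x == "-" or y == "-":
            counts["gap"] += 1
        elif (x in AMBIGUITY_CODES or y in AMBIGUITY_CODES) and \
                (IUPAC_SETS[x] & IUPAC_SETS[y]):
            counts["ambiguity"] += 1
        elif x == y:
            counts["match"] += 1
        else:
            counts["genuine_substitution"] += 1
    return counts


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
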