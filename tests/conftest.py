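"""Shared fixtures and independent oracle implementations.

The oracle functions here are deliberately naive (double loops, exhaustive
enumeration) and independent of the library code paths they check.
"""

from __future__ import annotations

import math

import pandas as pd
import pytest

from prefexp.data_io import ExpressionMatrix

# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "R": "AG", "Y": "CT",
    "S": "CG", "W": "AT", "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N",
         "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
         "B": "V", "V": "B", "D": "H", "H": "D"}


def naive_revcomp(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


def naive_scan(promoter: str, consensus: str, max_mismatches: int = 0):
    """Character-by-character double-loop consensus scan of both strands.

    Returns (offset, strand, matched, mismatches) tuples sorted by offset
    with '+' before '-' — the same reporting convention as the scanner under
    test, but none of its code.
    """
    w = len(consensus)
    hits = []
    for strand, pattern in (("+", consensus), ("-", naive_revcomp(consensus))):
        for off in range(len(promoter) - w + 1):
            window = promoter[off:off + w]
            mm = 0
            for a, b in zip(window, pattern):
                if a == "N" or a not in _IUPAC[b]:
                    mm += 1
            if mm <= max_mismatches:
                hits.append((off, strand, window, mm))
    hits.sort(key=lambda h: (h[0], h[1]))
    return hits


def enum_hypergeom_upper_tail(k: int, m: int, Q: int, G: int) -> float:
    """P(X >= k) by direct summation of the hypergeometric pmf with comb."""
    total = math.comb(G, Q)
    s = 0
    for i in range(k, min(m, Q) + 1):
        if Q - i <= G - m:
            s += math.comb(m, i) * math.comb(G - m, Q - i)
    return s / total


def f1_score(selected: set[str], truth: set[str]) -> float:
    tp = len(selected & truth)
    if not selected or not truth or tp == 0:
        return 0.0
    precision = tp / len(selected)
    recall = tp / len(truth)
    return 2 * precision * recall / (precision + recall)


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    """3 genes × 4 samples (2 tissues × 2 replicates), hand-written values."""
    values = pd.DataFrame(
        [[10.0, 10.2, 8.0, 8.2],
         [9.0, 9.4, 9.1, 9.3],
         [6.0, 6.2, 6.1, 5.9]],
        index=["g1", "g2", "g3"],
        columns=["rh_1", "rh_2", "rt_1", "rt_2"],
    )
    return ExpressionMatrix(
        values=values,
        sample_tissue={"rh_1": "root_hair", "rh_2": "root_hair",
                       "rt_1": "root", "rt_2": "root"},
        target_tissue="root_hair",
        reference_tissue="root",
    )


@pytest.fixture
def collapsed_panel() -> ExpressionMatrix:
    """5 genes × 4 tissues, already one column per tissue."""
    tissues = ["root_hair", "root", "leaf", "seed"]
    values = pd.DataFrame(
        [[12.0, 9.0, 6.0, 6.0],    # clean target-preferential, 8-fold
         [12.0, 11.5, 6.0, 6.0],   # fails the 2-fold rule
         [12.0, 9.0, 11.5, 6.0],   # also high in leaf
         [7.5, 7.0, 6.0, 6.0],     # below the expression threshold
         [10.0, 9.0, 8.0, 8.0]],   # exactly 2-fold over reference
        index=[f"g{i}" for i in range(1, 6)],
        columns=tissues,
    )
    return ExpressionMatrix(
        values=values,
        sample_tissue={t: t for t in tissues},
        target_tissue="root_hair",
        reference_tissue="root",
    )
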