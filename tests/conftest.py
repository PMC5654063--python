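"""Shared fixtures and independent oracles.

The folding oracle enumerates every pseudoknot-free set of canonical pairs
for short sequences; the alignment oracle enumerates every global alignment
of short strings.  Both are deliberately brute-force and independent of the
dynamic-programming implementations they check.
"""

from __future__ import annotations

import random

import pytest

from eiescreen import BarbellSpec, make_barbell_sequence
from eiescreen.rnastruct import MIN_HAIRPIN, _can_pair


def enumerate_structures(seq: str, min_hairpin: int = MIN_HAIRPIN, allow_gu: bool = True):
    """Yield every valid pseudoknot-free pair set (0-based pairs) of seq."""

    def rec(positions: tuple[int, ...]):
        if not positions:
            yield frozenset()
            return
        i, rest = positions[0], positions[1:]
        yield from rec(rest)  # i unpaired
        for j in rest:
            if j - i - 1 >= min_hairpin and _can_pair(seq[i], seq[j], allow_gu):
                inside = tuple(p for p in rest if i < p < j)
                outside = tuple(p for p in rest if p > j)
                for s1 in rec(inside):
                    for s2 in rec(outside):
                        yield s1 | s2 | {(i, j)}

    yield from rec(tuple(range(len(seq))))


def brute_force_best_score(
    seq: str,
    stacking_bonus: float = 0.0,
    min_hairpin: int = MIN_HAIRPIN,
    allow_gu: bool = True,
) -> float:
    """Maximum folding score by exhaustive enumeration (lengths <= ~12)."""
    best = 0.0
    for s in enumerate_structures(seq, min_hairpin, allow_gu):
        score = len(s) + stacking_bonus * sum(
            1 for (i, j) in s if (i + 1, j - 1) in s
        )
        best = max(best, score)
    return best


def brute_force_alignment_score(
    a: str, b: str, match: float = 1.0, mismatch: float = -1.0, gap: float = -2.0
) -> float:
    """Optimal global alignment score by exhaustive recursion (lengths <= ~8)."""

    def rec(i: int, j: int) -> float:
        if i == len(a):
            return gap * (len(b) - j)
        if j == len(b):
            return gap * (len(a) - i)
        diag = (match if a[i] == b[j] else mismatch) + rec(i + 1, j + 1)
        up = gap + rec(i + 1, j)
        left = gap + rec(i, j + 1)
        return max(diag, up, left)

    return rec(0, 0)


def random_rna(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGU") for _ in range(n))


@pytest.fixture(scope="session")
def glua2_fixture():
    """Barbell substrate built to the published description: 28-bp edited
    stem with two mismatches, 20+15 internal loop, 43-bp EIE with four
    mismatches and an 8-nt bulge, edit site 45 nt upstream of the EIE."""
    spec = BarbellSpec(substrate_id="GluA2_QR", seed=1)
    sequence, structure, edit_site = make_barbell_sequence(spec)
    return spec, sequence, structure, edit_site
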