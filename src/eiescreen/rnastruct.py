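"""Sequence and secondary-structure data model with FASTA/dot-bracket/CT I/O.

Coordinates are 1-based inclusive everywhere in this package, on the sense
strand of a single transcript.  A structure is a pseudoknot-free partial
matching of positions onto canonical pairs; the minimum hairpin length of
three unpaired nucleotides is enforced at construction.

The internal folder is a Nussinov-style base-pair maximiser with an optional
stacking bonus.  It is a deterministic structural oracle for designed and toy
substrates, not a thermodynamic model: real substrates are expected to arrive
with externally predicted structures in dot-bracket or CT form.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Iterator, TextIO

import numpy as np
from Bio import SeqIO

ALPHABET = frozenset("ACGU")

#: Watson-Crick pairs plus, optionally, G-U wobble.
WC_PAIRS = frozenset({("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")})
GU_PAIRS = frozenset({("G", "U"), ("U", "G")})
CANONICAL_PAIRS = WC_PAIRS | GU_PAIRS

#: Steric minimum number of unpaired nucleotides enclosed by any pair.
MIN_HAIRPIN = 3

_EPS = 1e-6  # float comparisons in the folding traceback


class StructureError(ValueError):
    """An invalid structure, or a structure file that cannot be parsed."""


def normalize_residues(raw: str) -> str:
    """Uppercase and apply the DNA->RNA convention T->U; validate alphabet."""
    residues = raw.upper().replace("T", "U")
    bad = set(residues) - ALPHABET
    if bad:
        raise ValueError(f"non-RNA residues after normalization: {sorted(bad)}")
    return residues


@dataclass(frozen=True)
class RnaSequence:
    """An RNA sequence with a text label; residues over {A, C, G, U}."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise ValueError(f"sequence {self.id!r}: empty record")
        bad = set(self.residues) - ALPHABET
        if bad:
            raise ValueError(
                f"sequence {self.id!r}: residues outside alphabet: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def base(self, position: int) -> str:
        """Residue at a 1-based position."""
        if not 1 <= position <= len(self.residues):
            raise IndexError(f"position {position} outside 1..{len(self.residues)}")
        return self.residues[position - 1]

    @classmethod
    def from_raw(cls, id: str, raw: str) -> "RnaSequence":
        return cls(id=id, residues=normalize_residues(raw))


@dataclass(frozen=True)
class RnaStructure:
    """A sequence plus a pseudoknot-free pair table.

    ``partner`` maps each 1-based position to its pairing partner, or 0 if
    unpaired.  Validation enforces involution, non-crossing and the minimum
    hairpin size.
    """

    sequence: RnaSequence
    partner: tuple[int, ...]

    def __post_init__(self) -> None:
        n = len(self.sequence)
        if len(self.partner) != n:
            raise StructureError(
                f"pair table length {len(self.partner)} != sequence length {n}"
            )
        for i, j in enumerate(self.partner, start=1):
            if j == 0:
                continue
            if not 1 <= j <= n:
                raise StructureError(f"position {i}: partner {j} out of range")
            if j == i:
                raise StructureError(f"position {i} pairs with itself")
            if self.partner[j - 1] != i:
                raise StructureError(
                    f"involution violated at positions {i}/{j}"
                )
            if abs(j - i) - 1 < MIN_HAIRPIN and j > i:
                raise StructureError(
                    f"pair ({i},{j}) encloses fewer than {MIN_HAIRPIN} nucleotides"
                )
        # non-crossing: pairs sorted by opening position must nest or precede
        stack: list[int] = []
        for i, j in enumerate(self.partner, start=1):
            if j > i:
                stack.append(j)
            elif 0 < j < i:
                if not stack or stack[-1] != i:
                    raise StructureError(f"crossing pair at position {i}")
                stack.pop()

    def __len__(self) -> int:
        return len(self.sequence)

    def pairs(self) -> list[tuple[int, int]]:
        """All pairs as (i, j) with i < j, ordered by i."""
        return [
            (i, j) for i, j in enumerate(self.partner, start=1) if j > i
        ]

    def is_paired(self, position: int) -> bool:
        return self.partner[position - 1] != 0

    def pair_count(self) -> int:
        return sum(1 for i, j in enumerate(self.partner, start=1) if j > i)

    def dotbracket(self) -> str:
        out = []
        for i, j in enumerate(self.partner, start=1):
            out.append("." if j == 0 else ("(" if j > i else ")"))
        return "".join(out)

    @classmethod
    def from_pairs(
        cls, sequence: RnaSequence, pairs: Iterable[tuple[int, int]]
    ) -> "RnaStructure":
        partner = [0] * len(sequence)
        for i, j in pairs:
            partner[i - 1] = j
            partner[j - 1] = i
        return cls(sequence=sequence, partner=tuple(partner))


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def parse_fasta(stream: TextIO | str) -> list[RnaSequence]:
    """Read a multi-record FASTA; T/lowercase are normalized, order preserved.

    Raises ``ValueError`` on an empty record body or a duplicate id.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(stream, "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id: {rec.id!r}")
        seen.add(rec.id)
        if len(rec.seq) == 0:
            raise ValueError(f"empty record: {rec.id!r}")
        records.append(RnaSequence.from_raw(rec.id, str(rec.seq)))
    return records


def write_fasta(sequences: Iterable[RnaSequence]) -> str:
    return "".join(f">{s.id}\n{s.residues}\n" for s in sequences)


# ---------------------------------------------------------------------------
# Dot-bracket (Vienna dialect)
# ---------------------------------------------------------------------------

def parse_dotbracket(sequence_line: str, structure_line: str, id: str = "seq") -> RnaStructure:
    """Build a structure from a sequence line and a matched-bracket line."""
    seq = RnaSequence.from_raw(id, sequence_line.strip())
    struct = structure_line.strip()
    if len(struct) != len(seq):
        raise StructureError(
            f"length mismatch: sequence {len(seq)} vs structure {len(struct)}"
        )
    bad = set(struct) - set("().")
    if bad:
        raise StructureError(f"invalid structure characters: {sorted(bad)}")
    depth = 0
    for pos, ch in enumerate(struct, start=1):
        depth += ch == "("
        depth -= ch == ")"
        if depth < 0:
            raise StructureError(f"unbalanced bracket at position {pos}")
    if depth != 0:
        raise StructureError(f"unbalanced brackets: {depth} unclosed")
    stack: list[int] = []
    pairs = []
    for pos, ch in enumerate(struct, start=1):
        if ch == "(":
            stack.append(pos)
        elif ch == ")":
            if not stack:
                raise StructureError(f"unbalanced bracket at position {pos}")
            i = stack.pop()
            if pos - i - 1 < MIN_HAIRPIN:
                raise StructureError(
                    f"pair ({i},{pos}) violates minimum hairpin at position {pos}"
                )
            pairs.append((i, pos))
    if stack:
        raise StructureError(f"unbalanced bracket at position {stack[-1]}")
    return RnaStructure.from_pairs(seq, pairs)


def read_dotbracket(stream: TextIO | str) -> list[RnaStructure]:
    """Read Vienna-style records: optional '>name' line, sequence, structure."""
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    lines = [ln.strip() for ln in stream if ln.strip()]
    out = []
    i = 0
    counter = 0
    while i < len(lines):
        if lines[i].startswith(">"):
            name = lines[i][1:].strip() or f"struct{counter}"
            i += 1
        else:
            name = f"struct{counter}"
        if i + 1 >= len(lines):
            raise StructureError("truncated dot-bracket record")
        out.append(parse_dotbracket(lines[i], lines[i + 1], id=name))
        i += 2
        counter += 1
    return out


def write_dotbracket(structure: RnaStructure) -> str:
    return (
        f">{structure.sequence.id}\n"
        f"{structure.sequence.residues}\n{structure.dotbracket()}\n"
    )


# ---------------------------------------------------------------------------
# CT (Zuker connectivity-table dialect)
# ---------------------------------------------------------------------------

def parse_ct(stream: TextIO | str) -> RnaStructure:
    """Parse a CT file: a header count line then one line per nucleotide
    (index, base, index-1, index+1, partner-or-0, index)."""
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    lines = [ln for ln in (raw.strip() for raw in stream) if ln]
    if not lines:
        raise StructureError("empty CT file")
    head = lines[0].split()
    try:
        n = int(head[0])
    except (ValueError, IndexError) as exc:
        raise StructureError(f"bad CT header line: {lines[0]!r}") from exc
    title = " ".join(head[1:]) or "ct"
    if len(lines) - 1 != n:
        raise StructureError(f"CT header declares {n} lines, found {len(lines) - 1}")
    residues = []
    partner = [0] * n
    for lineno, ln in enumerate(lines[1:], start=2):
        fields = ln.split()
        if len(fields) < 6:
            raise StructureError(f"line {lineno}: expected 6 CT columns")
        idx = int(fields[0])
        if idx != lineno - 1:
            raise StructureError(f"line {lineno}: index {idx} out of order")
        residues.append(fields[1])
        partner[idx - 1] = int(fields[4])
    for i, j in enumerate(partner, start=1):
        if j and partner[j - 1] != i:
            raise StructureError(
                f"line {i + 1}: partner {j} does not point back to {i}"
            )
    seq = RnaSequence.from_raw(title, "".join(residues))
    return RnaStructure(sequence=seq, partner=tuple(partner))


def write_ct(structure: RnaStructure) -> str:
    seq = structure.sequence
    n = len(seq)
    lines = [f"{n} {seq.id}"]
    for i in range(1, n + 1):
        lines.append(
            f"{i} {seq.base(i)} {i - 1} {(i + 1) % (n + 1)} "
            f"{structure.partner[i - 1]} {i}"
        )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Folding: base-pair maximization with optional stacking bonus
# ---------------------------------------------------------------------------

def _can_pair(a: str, b: str, allow_gu: bool) -> bool:
    pair = (a, b)
    return pair in WC_PAIRS or (allow_gu and pair in GU_PAIRS)


def fold(
    sequence: RnaSequence,
    min_hairpin: int = MIN_HAIRPIN,
    allow_gu: bool = True,
    stacking_bonus: float = 0.5,
) -> RnaStructure:
    """Maximum-score pseudoknot-free structure over canonical pairs.

    The score of a structure is its pair count plus ``stacking_bonus`` for
    every pair stacked directly on another ((i, j) with (i+1, j-1) also
    paired).  The traceback is deterministic: stacking is extended first, and
    otherwise each position pairs with its smallest admissible partner.

    Dynamic programming uses three interval tables.  ``P[i, j]`` is the best
    score of i..j given (i, j) paired; ``X[i, j]`` the best score with i NOT
    paired to j; ``M[i, j]`` the unconstrained best.
    """
    n = len(sequence)
    if n < min_hairpin + 2:
        raise ValueError(
            f"sequence of length {n} cannot fold with min_hairpin={min_hairpin}"
        )
    res = sequence.residues
    neg = -1e9

    can = np.zeros((n, n), dtype=bool)  # 0-based
    for i in range(n):
        for j in range(i + min_hairpin + 1, n):
            can[i, j] = _can_pair(res[i], res[j], allow_gu)

    P = np.full((n + 1, n + 1), neg)
    M = np.zeros((n + 1, n + 1))
    X = np.zeros((n + 1, n + 1))

    for span in range(min_hairpin + 1, n):
        for i in range(0, n - span):
            j = i + span
            if can[i, j]:
                inner_stack = P[i + 1, j - 1] + stacking_bonus
                inner_open = X[i + 1, j - 1] if j - 1 >= i + 1 else 0.0
                P[i, j] = 1.0 + max(inner_stack, inner_open)
            # X: i unpaired, or i paired with some k < j
            best = M[i + 1, j]
            ks = np.nonzero(can[i, i:j])[0] + i  # candidate partners k in i..j-1
            if ks.size:
                vals = P[i, ks] + M[ks + 1, j]
                best = max(best, float(vals.max()))
            X[i, j] = best
            M[i, j] = max(X[i, j], P[i, j])

    pairs: list[tuple[int, int]] = []

    def trace_M(i: int, j: int) -> None:
        while i < j:
            if M[i, j] <= _EPS:
                return
            # prefer pairing i with the smallest admissible partner
            target = M[i, j]
            paired = False
            for k in range(i + min_hairpin + 1, j + 1):
                if can[i, k] and P[i, k] + M[k + 1, j] >= target - _EPS:
                    trace_P(i, k)
                    i = k + 1
                    paired = True
                    break
            if not paired:
                i += 1

    def trace_P(i: int, j: int) -> None:
        while True:
            pairs.append((i + 1, j + 1))  # back to 1-based
            inner = P[i, j] - 1.0
            if inner <= _EPS:
                return
            if (
                j - 1 >= i + 1
                and can[i + 1, j - 1]
                and P[i + 1, j - 1] + stacking_bonus >= inner - _EPS
            ):
                i, j = i + 1, j - 1  # stacked continuation
            else:
                trace_M(i + 1, j - 1)
                return

    trace_M(0, n - 1)
    return RnaStructure.from_pairs(sequence, pairs)


_COMPLEMENT = str.maketrans("ACGU", "UGCA")


def mirror(structure: RnaStructure) -> RnaStructure:
    """Reverse-complement mirror: position k maps to n+1-k, pairs preserved."""
    n = len(structure)
    seq = RnaSequence(
        id=structure.sequence.id + "_mirror",
        residues=structure.sequence.residues.translate(_COMPLEMENT)[::-1],
    )
    partner = [0] * n
    for k in range(1, n + 1):
        p = structure.partner[n - k]
        partner[k - 1] = 0 if p == 0 else n + 1 - p
    return RnaStructure(sequence=seq, partner=tuple(partner))


def fold_score(structure: RnaStructure, stacking_bonus: float = 0.5) -> float:
    """Score of an explicit structure under the folder's objective."""
    score = 0.0
    for i, j in structure.pairs():
        score += 1.0
        if structure.partner[i] == j - 1 and j - 1 > i + 1:  # (i+1, j-1) paired
            score += stacking_bonus
    return score
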