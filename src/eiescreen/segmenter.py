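"""Decomposition of a pair table into stems, loops and bulges.

The segmentation follows the ADAR helix-end rule: small interruptions of a
helix (bulges, mismatches, internal loops of up to ``merge_tolerance``
unpaired nucleotides in total, default 4) are treated as part of one
continuous stem, while larger internal loops (above ``helix_end_threshold``,
default 6) terminate it.  Interruption totals falling strictly between the
two thresholds are conservatively treated as helix ends (boundary policy:
not merged), so the effective merge rule for internal interruptions is
"merge iff total <= merge_tolerance".

The helix-end rule is a rule about internal loops, i.e. interruptions with
unpaired nucleotides on BOTH strands.  One-sided bulges do not present a
helix end and are merged regardless of size by default (``merge_bulges``):
a 43-bp stem carrying four mismatches and an 8-nt bulge is one 102-nt stem,
not two.

Loop sizes are counted as total unpaired nucleotides across both strands of
the interruption: a 20+15 internal loop counts as 35 nt.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

from .rnastruct import RnaStructure

MERGE_TOLERANCE = 4
HELIX_END_THRESHOLD = 6


@dataclass(frozen=True)
class Helix:
    """A maximal run of stacked pairs (i,j), (i+1,j-1), ..."""

    pairs: tuple[tuple[int, int], ...]

    @property
    def bp_count(self) -> int:
        return len(self.pairs)

    @property
    def outer(self) -> tuple[int, int]:
        return self.pairs[0]

    @property
    def inner(self) -> tuple[int, int]:
        return self.pairs[-1]


@dataclass(frozen=True)
class Interruption:
    """Unpaired nucleotides interrupting a merged stem.

    A bulge has unpaired nucleotides on exactly one strand; a mismatch is
    1+1; anything else small enough to merge is a small internal loop.
    """

    left_unpaired: int
    right_unpaired: int

    @property
    def total(self) -> int:
        return self.left_unpaired + self.right_unpaired

    @property
    def kind(self) -> str:
        if self.left_unpaired == 0 or self.right_unpaired == 0:
            return "bulge"
        if self.left_unpaired == 1 and self.right_unpaired == 1:
            return "mismatch"
        return "small_internal_loop"


@dataclass(frozen=True)
class StemSegment:
    """Helices merged across small interruptions into one duplex region.

    ``span_5p`` and ``span_3p`` are 1-based inclusive ranges on each strand,
    including the merged interruption nucleotides.  ``length_nt`` counts the
    nucleotides of both strands, the convention used for stem lengths
    throughout the package (e.g. a 43-bp stem with four mismatches and an
    8-nt bulge spans 102 nt).
    """

    helices: tuple[Helix, ...]
    interruptions: tuple[Interruption, ...]

    @property
    def bp_count(self) -> int:
        return sum(h.bp_count for h in self.helices)

    @property
    def span_5p(self) -> tuple[int, int]:
        return (self.helices[0].outer[0], self.helices[-1].inner[0])

    @property
    def span_3p(self) -> tuple[int, int]:
        return (self.helices[-1].inner[1], self.helices[0].outer[1])

    @property
    def length_nt(self) -> int:
        (s5, e5), (s3, e3) = self.span_5p, self.span_3p
        return (e5 - s5 + 1) + (e3 - s3 + 1)

    @property
    def paired_fraction(self) -> float:
        return 2 * self.bp_count / self.length_nt

    @property
    def positions(self) -> frozenset[int]:
        (s5, e5), (s3, e3) = self.span_5p, self.span_3p
        return frozenset(range(s5, e5 + 1)) | frozenset(range(s3, e3 + 1))

    def contains(self, position: int) -> bool:
        (s5, e5), (s3, e3) = self.span_5p, self.span_3p
        return s5 <= position <= e5 or s3 <= position <= e3

    @property
    def kind(self) -> str:
        return "stem"


@dataclass(frozen=True)
class InternalLoopSegment:
    """Unpaired nucleotides on both strands separating two stems."""

    left_range: tuple[int, int]   # 5'-strand unpaired run (start, end); (0, -1) if empty
    right_range: tuple[int, int]  # 3'-strand unpaired run

    @property
    def left_unpaired(self) -> int:
        s, e = self.left_range
        return max(0, e - s + 1)

    @property
    def right_unpaired(self) -> int:
        s, e = self.right_range
        return max(0, e - s + 1)

    @property
    def total(self) -> int:
        return self.left_unpaired + self.right_unpaired

    @property
    def positions(self) -> frozenset[int]:
        out: set[int] = set()
        for s, e in (self.left_range, self.right_range):
            out.update(range(s, e + 1))
        return frozenset(out)

    @property
    def kind(self) -> str:
        return "internal_loop"


@dataclass(frozen=True)
class LoopSegment:
    """A hairpin loop, multibranch junction or exterior unpaired run."""

    kind: str  # hairpin | multibranch | exterior
    positions: frozenset[int]


Segment = StemSegment | InternalLoopSegment | LoopSegment


@dataclass(frozen=True)
class SegmentedStructure:
    """Ordered decomposition of a structure into disjoint segments."""

    structure: RnaStructure
    segments: tuple[Segment, ...]

    def stems(self) -> list[StemSegment]:
        return [s for s in self.segments if isinstance(s, StemSegment)]

    def internal_loops(self) -> list[InternalLoopSegment]:
        return [s for s in self.segments if isinstance(s, InternalLoopSegment)]

    def __iter__(self) -> Iterator[Segment]:
        return iter(self.segments)


def find_helices(structure: RnaStructure) -> list[Helix]:
    """Maximal stacked runs of pairs, disjoint, ordered by 5' start."""
    pairs = structure.pairs()
    pairset = set(pairs)
    helices = []
    seen: set[tuple[int, int]] = set()
    for i, j in pairs:
        if (i, j) in seen:
            continue
        if (i - 1, j + 1) in pairset:
            continue  # not the outer pair of its run
        run = [(i, j)]
        while (run[-1][0] + 1, run[-1][1] - 1) in pairset:
            run.append((run[-1][0] + 1, run[-1][1] - 1))
        seen.update(run)
        helices.append(Helix(pairs=tuple(run)))
    return helices


def _children(helix: Helix, helices: list[Helix]) -> list[Helix]:
    """Direct descendants: helices nested immediately inside ``helix``."""
    ci, cj = helix.inner
    inside = [h for h in helices if ci < h.outer[0] and h.outer[1] < cj]
    # keep only those not nested in another inside helix
    out = []
    for h in inside:
        if not any(
            g is not h and g.outer[0] < h.outer[0] and h.outer[1] < g.outer[1]
            for g in inside
        ):
            out.append(h)
    return sorted(out, key=lambda h: h.outer[0])


def segment(
    structure: RnaStructure,
    merge_tolerance: int = MERGE_TOLERANCE,
    helix_end_threshold: int = HELIX_END_THRESHOLD,
    merge_bulges: bool = True,
) -> SegmentedStructure:
    """Segment a structure into stems, internal loops and loop regions.

    Adjacent nested helices whose intervening unpaired total is at most
    ``merge_tolerance`` merge into one :class:`StemSegment`; larger totals
    become :class:`InternalLoopSegment` boundaries (totals between the two
    thresholds are treated as helix ends; see module docstring).
    """
    if merge_tolerance >= helix_end_threshold:
        raise ValueError("merge_tolerance must be < helix_end_threshold")
    n = len(structure)
    helices = find_helices(structure)
    segments: list[Segment] = []

    def walk_chain(start: Helix) -> None:
        """Build the stem beginning at ``start``, then recurse inward."""
        chain = [start]
        interruptions: list[Interruption] = []
        while True:
            cur = chain[-1]
            kids = _children(cur, helices)
            if len(kids) == 1:
                kid = kids[0]
                left = kid.outer[0] - cur.inner[0] - 1
                right = cur.inner[1] - kid.outer[1] - 1
                is_bulge = left == 0 or right == 0
                if (is_bulge and merge_bulges) or left + right <= merge_tolerance:
                    interruptions.append(Interruption(left, right))
                    chain.append(kid)
                    continue
            break
        stem = StemSegment(helices=tuple(chain), interruptions=tuple(interruptions))
        segments.append(stem)
        cur = chain[-1]
        ci, cj = cur.inner
        kids = _children(cur, helices)
        if not kids:
            segments.append(
                LoopSegment("hairpin", frozenset(range(ci + 1, cj - 1 + 1)))
            )
        elif len(kids) == 1:
            kid = kids[0]
            segments.append(
                InternalLoopSegment(
                    left_range=(ci + 1, kid.outer[0] - 1),
                    right_range=(kid.outer[1] + 1, cj - 1),
                )
            )
            walk_chain(kid)
        else:
            junction = set(range(ci + 1, cj))
            for kid in kids:
                junction -= set(range(kid.outer[0], kid.outer[1] + 1))
                walk_chain(kid)
            if junction:
                segments.append(LoopSegment("multibranch", frozenset(junction)))

    top = [
        h
        for h in helices
        if not any(
            g.outer[0] < h.outer[0] and h.outer[1] < g.outer[1] for g in helices
        )
    ]
    covered: set[int] = set()
    for h in top:
        covered.update(range(h.outer[0], h.outer[1] + 1))
        walk_chain(h)
    exterior = sorted(set(range(1, n + 1)) - covered)
    if exterior:
        # group maximal runs
        run = [exterior[0]]
        for p in exterior[1:]:
            if p == run[-1] + 1:
                run.append(p)
            else:
                segments.append(LoopSegment("exterior", frozenset(run)))
                run = [p]
        segments.append(LoopSegment("exterior", frozenset(run)))

    segments.sort(key=lambda s: min(s.positions) if s.positions else 0)
    return SegmentedStructure(structure=structure, segments=tuple(segments))


def stem_at(segmented: SegmentedStructure, position: int) -> Optional[StemSegment]:
    """The unique stem whose spans contain ``position``, or None."""
    if not 1 <= position <= len(segmented.structure):
        raise IndexError(
            f"position {position} outside 1..{len(segmented.structure)}"
        )
    for stem in segmented.stems():
        if stem.contains(position):
            return stem
    return None


def segments_to_tsv(segmented: SegmentedStructure) -> str:
    """TSV report: one row per segment with spans and unpaired counts."""
    rows = ["segment_kind\tstart_5p\tend_5p\tstart_3p\tend_3p\tbp_count\tleft_unpaired\tright_unpaired"]
    for seg in segmented.segments:
        if isinstance(seg, StemSegment):
            (s5, e5), (s3, e3) = seg.span_5p, seg.span_3p
            rows.append(
                f"stem\t{s5}\t{e5}\t{s3}\t{e3}\t{seg.bp_count}\t0\t0"
            )
        elif isinstance(seg, InternalLoopSegment):
            (s5, e5), (s3, e3) = seg.left_range, seg.right_range
            rows.append(
                f"internal_loop\t{s5}\t{e5}\t{s3}\t{e3}\t0\t"
                f"{seg.left_unpaired}\t{seg.right_unpaired}"
            )
        else:
            lo = min(seg.positions) if seg.positions else 0
            hi = max(seg.positions) if seg.positions else -1
            rows.append(f"{seg.kind}\t{lo}\t{hi}\t\t\t0\t{len(seg.positions)}\t0")
    return "\n".join(rows) + "\n"
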