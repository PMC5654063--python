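"""Editing quantification from Sanger peak heights and reporter-construct
coordinate operations.

The percentage of editing at a site is 100*G/(A+G) from the A and G peak
heights of the chromatogram; replicate experiments are summarized as mean
and sample (n-1) standard deviation.  Peak heights arrive as TSV columns
(substrate_id, offset, replicate, height_A, height_G); binary trace parsing
is out of scope.

Coordinates here are relative: the edit site is offset 0 and "+k" is k nt
3' (downstream) of it, negative offsets 5'.  Deletion ranges are inclusive
at both ends, so deleting +24..+44 and +276..+291 removes 21 + 16 = 37 nt.
Relocation excises a segment and reinserts it so that a requested number of
nucleotides separates it from the edit site on the chosen side, preserving
total length and residue content; both operations return a coordinate map
so structures and annotations can follow the construct.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, TextIO

import pandas as pd

from .eiescan import EditSite
from .rnastruct import RnaSequence, RnaStructure


@dataclass(frozen=True)
class PeakRecord:
    """A and G peak heights at one site in one replicate chromatogram."""

    substrate_id: str
    offset: int
    replicate: int
    height_A: float
    height_G: float

    def __post_init__(self) -> None:
        if self.height_A < 0 or self.height_G < 0:
            raise ValueError("peak heights must be non-negative")


@dataclass(frozen=True)
class EditingMeasurement:
    """Replicate summary of editing at one site; sd is the sample (n-1)
    standard deviation, reported as 0 for a single replicate (n=1)."""

    offset: int
    percents: tuple[float, ...]
    mean: float
    sd: float
    n: int


@dataclass(frozen=True)
class DeletionSpec:
    """Inclusive relative ranges to delete, pairwise disjoint."""

    ranges: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        for a, b in self.ranges:
            if a > b:
                raise ValueError(f"deletion range ({a},{b}) has from > to")
        ordered = sorted(self.ranges)
        for (a1, b1), (a2, b2) in zip(ordered, ordered[1:]):
            if a2 <= b1:
                raise ValueError(
                    f"overlapping deletion ranges ({a1},{b1}) and ({a2},{b2})"
                )


@dataclass(frozen=True)
class RelocationSpec:
    """Excise the inclusive relative range [start, end] and reinsert it with
    exactly ``gap_nt`` nucleotides between the segment and the edit site, on
    the 5' side if ``side`` is "5p" (e.g. the construct that moves a
    downstream EIE to 50 nt upstream of the edit site)."""

    start: int
    end: int
    gap_nt: int
    side: str = "5p"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("relocation segment has start > end")
        if self.start <= 0 <= self.end:
            raise ValueError("relocation segment covers the edit site")
        if self.gap_nt < 0:
            raise ValueError("gap_nt must be >= 0")
        if self.side not in ("5p", "3p"):
            raise ValueError("side must be '5p' or '3p'")


def percent_editing(height_A: float, height_G: float) -> float:
    """Editing percentage from peak heights: 100*G/(A+G)."""
    if height_A < 0 or height_G < 0:
        raise ValueError("peak heights must be non-negative")
    total = height_A + height_G
    if total == 0:
        raise ValueError("unquantifiable site: A + G peak heights are zero")
    return 100.0 * height_G / total


def summarize(records: Sequence[PeakRecord]) -> list[EditingMeasurement]:
    """Per-site replicate summaries (mean, sample sd), ordered by offset."""
    if not records:
        raise ValueError("no peak records to summarize")
    by_site: dict[int, list[PeakRecord]] = {}
    for rec in records:
        by_site.setdefault(rec.offset, []).append(rec)
    out = []
    for offset in sorted(by_site):
        group = sorted(by_site[offset], key=lambda r: r.replicate)
        percents = tuple(percent_editing(r.height_A, r.height_G) for r in group)
        n = len(percents)
        mean = sum(percents) / n
        if n > 1:
            sd = math.sqrt(sum((p - mean) ** 2 for p in percents) / (n - 1))
        else:
            sd = 0.0
        out.append(
            EditingMeasurement(offset=offset, percents=percents, mean=mean, sd=sd, n=n)
        )
    return out


def deletion_length(spec: DeletionSpec | Iterable[tuple[int, int]]) -> int:
    """Total nucleotides removed: sum of (to - from + 1) over the ranges."""
    if not isinstance(spec, DeletionSpec):
        spec = DeletionSpec(ranges=tuple(spec))
    return sum(b - a + 1 for a, b in spec.ranges)


@dataclass(frozen=True)
class CoordinateMap:
    """Old -> new 1-based absolute positions (deleted positions absent)."""

    old_to_new: dict[int, int]
    new_edit_position: int

    def new_position(self, old_position: int) -> Optional[int]:
        return self.old_to_new.get(old_position)

    def old_position(self, new_position: int) -> Optional[int]:
        for old, new in self.old_to_new.items():
            if new == new_position:
                return old
        return None


def _check_spec_bounds(
    spec_ranges: Iterable[tuple[int, int]], edit_site: EditSite, n: int
) -> None:
    for a, b in spec_ranges:
        if a <= 0 <= b:
            raise ValueError("edit site deleted: range covers offset 0")
        lo, hi = edit_site.absolute(a), edit_site.absolute(b)
        if lo < 1 or hi > n:
            raise ValueError(
                f"range ({a},{b}) falls outside the sequence (abs {lo}..{hi})"
            )


def apply_deletion(
    sequence: RnaSequence,
    edit_site: EditSite,
    spec: DeletionSpec | Iterable[tuple[int, int]],
) -> tuple[RnaSequence, CoordinateMap]:
    """Remove the spec's ranges; the edit site must survive.

    Returns the shortened sequence and a coordinate map for the surviving
    positions.  An empty spec yields the identity map.
    """
    if not isinstance(spec, DeletionSpec):
        spec = DeletionSpec(ranges=tuple(spec))
    n = len(sequence)
    _check_spec_bounds(spec.ranges, edit_site, n)
    deleted: set[int] = set()
    for a, b in spec.ranges:
        deleted.update(range(edit_site.absolute(a), edit_site.absolute(b) + 1))
    old_to_new: dict[int, int] = {}
    residues = []
    new_pos = 0
    for old in range(1, n + 1):
        if old in deleted:
            continue
        new_pos += 1
        old_to_new[old] = new_pos
        residues.append(sequence.residues[old - 1])
    new_seq = RnaSequence(
        id=f"{sequence.id}_del{deletion_length(spec)}", residues="".join(residues)
    )
    cmap = CoordinateMap(
        old_to_new=old_to_new, new_edit_position=old_to_new[edit_site.position]
    )
    return new_seq, cmap


def apply_relocation(
    sequence: RnaSequence,
    edit_site: EditSite,
    spec: RelocationSpec,
) -> tuple[RnaSequence, CoordinateMap]:
    """Excise the segment and reinsert it at the requested side and gap.

    Total length and residue multiset are preserved.  Relocating a segment
    onto its original locus is the identity.  Raises if the target would
    fall outside the sequence or collide with the edit site.
    """
    n = len(sequence)
    _check_spec_bounds([(spec.start, spec.end)], edit_site, n)
    seg_lo = edit_site.absolute(spec.start)
    seg_hi = edit_site.absolute(spec.end)
    segment = list(range(seg_lo, seg_hi + 1))
    remaining = [p for p in range(1, n + 1) if not seg_lo <= p <= seg_hi]
    e_idx = remaining.index(edit_site.position)  # 0-based index in remaining
    if spec.side == "5p":
        k = e_idx - spec.gap_nt
        if k < 0:
            raise ValueError(
                f"relocation target {spec.gap_nt} nt upstream falls outside "
                "the sequence"
            )
    else:
        k = e_idx + 1 + spec.gap_nt
        if k > len(remaining):
            raise ValueError(
                f"relocation target {spec.gap_nt} nt downstream falls outside "
                "the sequence"
            )
    new_order = remaining[:k] + segment + remaining[k:]
    old_to_new = {old: new for new, old in enumerate(new_order, start=1)}
    residues = "".join(sequence.residues[old - 1] for old in new_order)
    new_seq = RnaSequence(id=f"{sequence.id}_reloc", residues=residues)
    cmap = CoordinateMap(
        old_to_new=old_to_new, new_edit_position=old_to_new[edit_site.position]
    )
    return new_seq, cmap


def remap_structure(
    structure: RnaStructure, new_sequence: RnaSequence, cmap: CoordinateMap
) -> RnaStructure:
    """Carry a structure through a construct operation.

    Pairs whose both endpoints survive are kept at their mapped positions;
    pairs losing an endpoint are dropped.  Pairs that would violate the
    minimum hairpin after the operation are dropped as well (the construct
    physically removed the loop they enclosed).
    """
    pairs = []
    for i, j in structure.pairs():
        ni, nj = cmap.new_position(i), cmap.new_position(j)
        if ni is None or nj is None:
            continue
        lo, hi = min(ni, nj), max(ni, nj)
        if hi - lo - 1 < 3:
            continue
        pairs.append((lo, hi))
    return RnaStructure.from_pairs(new_sequence, pairs)


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

PEAK_COLUMNS = ["substrate_id", "offset", "replicate", "height_A", "height_G"]


def read_peaks_tsv(stream: TextIO | str) -> list[PeakRecord]:
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    df = pd.read_csv(stream, sep="\t")
    missing = set(PEAK_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"peak TSV missing columns: {sorted(missing)}")
    return [
        PeakRecord(
            substrate_id=str(r.substrate_id),
            offset=int(r.offset),
            replicate=int(r.replicate),
            height_A=float(r.height_A),
            height_G=float(r.height_G),
        )
        for r in df.itertuples()
    ]


def write_peaks_tsv(records: Sequence[PeakRecord]) -> str:
    df = pd.DataFrame([r.__dict__ for r in records], columns=PEAK_COLUMNS)
    return df.to_csv(sep="\t", index=False)


def measurements_to_tsv(measurements: Sequence[EditingMeasurement]) -> str:
    rows = ["offset\tn\tmean_percent\tsd"]
    for m in measurements:
        rows.append(f"{m.offset}\t{m.n}\t{m.mean:.6g}\t{m.sd:.6g}")
    return "\n".join(rows) + "\n"
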