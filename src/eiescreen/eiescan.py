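"""Detection of editing inducer elements (EIEs) flanking an edit site.

An EIE is a long, stable stem adjacent to — but structurally separate from —
the shorter stem containing a selectively edited adenosine.  Given a
segmented structure and an edit site this module locates the edited stem,
collects flanking candidate stems, computes the screening metrics (stem
length in nt over both strands, base-pair count, transcript distance to the
edit site, 5'/3' side), applies the stability criterion, and classifies
substrates by measured editing efficiency (high >= 50%, low <= 45%).

The default minimum of 20 bp for an EIE reflects the duplex length
sufficient for the ADAR deaminase domain to engage a substrate.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

from .segmenter import SegmentedStructure, StemSegment, stem_at

MIN_EIE_BP = 20
MIN_PAIRED_FRACTION = 0.6
HIGH_EFFICIENCY_MIN = 50.0
LOW_EFFICIENCY_MAX = 45.0


class UnpairedEditSiteError(ValueError):
    """The edit site lies in a loop or exterior region: the structure cannot
    support the barbell model (no edited stem to anchor the scan)."""


@dataclass(frozen=True)
class EditSite:
    """A substrate's edited position, 1-based on the transcript.

    By convention the edit site itself is relative offset 0 and other
    positions are expressed as offsets, downstream positive (+4, +60, ...).
    """

    substrate_id: str
    position: int
    amino_acid_change: Optional[str] = None  # e.g. "Q/R", "I/M"

    def offset_of(self, position: int) -> int:
        return position - self.position

    def absolute(self, offset: int) -> int:
        return self.position + offset


@dataclass(frozen=True)
class EieCandidate:
    """A flanking stem evaluated as a potential EIE."""

    stem: StemSegment
    side: str          # "5p" or "3p" of the edit site
    length_nt: int     # nucleotides in the stem spans, both strands
    bp_count: int
    distance_nt: int   # nt strictly between edit site and nearest stem nt
    stable: Optional[bool] = None


@dataclass(frozen=True)
class EieReport:
    """One screening row: efficiency class, conservation/stability calls and
    the flanking stem candidates for a single substrate."""

    substrate_id: str
    edit_site: EditSite
    editing_percent: float
    efficiency_class: str                 # high | low | unclassified
    conserved_adjacent_stem: str          # yes | no | not_determined
    stable_adjacent_stem: str             # yes | no | not_determined
    candidates: tuple[EieCandidate, ...]
    structure_source: str = "given"       # given | folded

    @property
    def has_eie(self) -> bool:
        return len(self.candidates) > 0


def identify_edited_stem(
    segmented: SegmentedStructure, edit_site: EditSite
) -> StemSegment:
    """The stem whose spans (including merged interruptions) contain the
    edit site.  Raises :class:`UnpairedEditSiteError` if the site falls in
    a loop or exterior region."""
    stem = stem_at(segmented, edit_site.position)
    if stem is None:
        raise UnpairedEditSiteError(
            f"{edit_site.substrate_id}: edit site at position "
            f"{edit_site.position} is not within any stem"
        )
    return stem


def _distance_and_side(stem: StemSegment, position: int) -> tuple[int, str]:
    nearest = min(stem.positions, key=lambda p: abs(p - position))
    return abs(nearest - position) - 1, ("3p" if nearest > position else "5p")


def find_eie_candidates(
    segmented: SegmentedStructure,
    edit_site: EditSite,
    min_bp: int = MIN_EIE_BP,
) -> list[EieCandidate]:
    """Flanking stems that could act as EIEs, sorted by distance.

    A candidate is any stem other than the edited stem with at least
    ``min_bp`` base pairs that is separated from the edit site by at least
    one loop-region nucleotide (the structural separation that makes it an
    independent duplex rather than a continuation of the edited stem).
    Returns an empty list when no flanking stem qualifies (e.g. EIE-deletion
    constructs).
    """
    edited = identify_edited_stem(segmented, edit_site)
    loop_positions: set[int] = set()
    for seg in segmented.segments:
        if not isinstance(seg, StemSegment):
            loop_positions.update(seg.positions)

    out = []
    for stem in segmented.stems():
        if stem == edited or stem.bp_count < min_bp:
            continue
        distance, side = _distance_and_side(stem, edit_site.position)
        lo = min(stem.positions, key=lambda p: abs(p - edit_site.position))
        between = (
            set(range(edit_site.position + 1, lo))
            if lo > edit_site.position
            else set(range(lo + 1, edit_site.position))
        )
        if not between & loop_positions:
            continue  # contiguous with the edited stem, not a separate duplex
        out.append(
            EieCandidate(
                stem=stem,
                side=side,
                length_nt=stem.length_nt,
                bp_count=stem.bp_count,
                distance_nt=distance,
            )
        )
    out.sort(key=lambda c: (c.distance_nt, c.side))
    return out


def stability_check(
    candidate: EieCandidate,
    min_bp: int = MIN_EIE_BP,
    min_paired_fraction: float = MIN_PAIRED_FRACTION,
) -> bool:
    """A stem is called stable when it is long enough to engage the enzyme
    (>= ``min_bp`` pairs) and predominantly double-stranded
    (paired fraction of its span >= ``min_paired_fraction``)."""
    return (
        candidate.bp_count >= min_bp
        and candidate.stem.paired_fraction >= min_paired_fraction
    )


def classify_efficiency(editing_percent: float) -> str:
    """high (>= 50%), low (<= 45%), else unclassified; the 45-50% gap is the
    deliberate margin between the two published efficiency classes."""
    if not 0.0 <= editing_percent <= 100.0:
        raise ValueError(f"editing percent {editing_percent} outside 0..100")
    if editing_percent >= HIGH_EFFICIENCY_MIN:
        return "high"
    if editing_percent <= LOW_EFFICIENCY_MAX:
        return "low"
    return "unclassified"


def build_report(
    substrate_id: str,
    segmented: SegmentedStructure,
    edit_site: EditSite,
    editing_percent: float,
    conservation_verdict: Optional[str] = None,
    min_bp: int = MIN_EIE_BP,
    min_paired_fraction: float = MIN_PAIRED_FRACTION,
    structure_source: str = "given",
) -> EieReport:
    """Assemble one screening row from the computed components.

    ``conservation_verdict`` is reported alongside (yes/no/not_determined)
    and never gates candidate detection: conservation and stability are
    separate columns of the screen.
    """
    efficiency = classify_efficiency(editing_percent)
    try:
        candidates = find_eie_candidates(segmented, edit_site, min_bp=min_bp)
    except UnpairedEditSiteError:
        candidates = []
    candidates = [
        replace(c, stable=stability_check(c, min_bp, min_paired_fraction))
        for c in candidates
    ]
    if candidates:
        stable = "yes" if any(c.stable for c in candidates) else "no"
    else:
        stable = "not_determined"
    conserved = conservation_verdict if conservation_verdict else "not_determined"
    return EieReport(
        substrate_id=substrate_id,
        edit_site=edit_site,
        editing_percent=editing_percent,
        efficiency_class=efficiency,
        conserved_adjacent_stem=conserved,
        stable_adjacent_stem=stable,
        candidates=tuple(candidates),
        structure_source=structure_source,
    )
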