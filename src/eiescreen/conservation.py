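"""Ortholog conservation of EIE regions.

Compensatory double substitutions at pairing partners, wobble-preserving
single substitutions and changes confined to loops all leave the duplex
intact; substitutions that break a canonical pair are disruptive.  A region
whose ortholog differences are (almost) exclusively structure-preserving is
called conserved: the operational criterion is sequence identity >=
``min_identity`` (default 0.85) and disruptive changes in at most
``max_disruptive_fraction`` (default 0.05) of the paired columns.  Both
thresholds are explicit parameters reported in the verdict, since "conserved"
is a qualitative published call being operationalized here.

Alignment is global (Needleman-Wunsch) with linear gap scoring, defaults
match +1 / mismatch -1 / gap -2, delegated to Bio.Align.PairwiseAligner.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from Bio import Align

from .rnastruct import CANONICAL_PAIRS, RnaSequence, RnaStructure

MIN_IDENTITY = 0.85
MAX_DISRUPTIVE_FRACTION = 0.05

GAP = "-"

#: substitution classes, in reporting order
CLASSES = (
    "compensatory",
    "wobble_preserving",
    "loop_located",
    "disruptive",
    "indel",
)


@dataclass(frozen=True)
class OrthologPair:
    """Two orthologous sequences over the same substrate region, aligned."""

    species_a: RnaSequence
    species_b: RnaSequence
    aligned_a: str
    aligned_b: str
    score: float

    def __post_init__(self) -> None:
        if self.aligned_a.replace(GAP, "") != self.species_a.residues:
            raise ValueError("alignment row a does not degap to species_a")
        if self.aligned_b.replace(GAP, "") != self.species_b.residues:
            raise ValueError("alignment row b does not degap to species_b")

    @property
    def n_columns(self) -> int:
        return len(self.aligned_a)

    def positions_a(self) -> list[Optional[int]]:
        """1-based species_a position per column, None at gap columns."""
        out: list[Optional[int]] = []
        p = 0
        for ch in self.aligned_a:
            if ch == GAP:
                out.append(None)
            else:
                p += 1
                out.append(p)
        return out

    def positions_b(self) -> list[Optional[int]]:
        out: list[Optional[int]] = []
        p = 0
        for ch in self.aligned_b:
            if ch == GAP:
                out.append(None)
            else:
                p += 1
                out.append(p)
        return out


@dataclass(frozen=True)
class SubstitutionRecord:
    """One non-identical alignment column, classified structurally.

    The class is a function of the two residues, the partner residues and
    the paired/unpaired status of the species_a position only.
    """

    column: int                      # 1-based alignment column
    position_a: Optional[int]
    position_b: Optional[int]
    residue_a: str                   # '-' for an insertion in b
    residue_b: str
    klass: str                       # one of CLASSES


@dataclass(frozen=True)
class OrthologComparison:
    """Aligned ortholog pair plus per-substitution classification."""

    pair: OrthologPair
    records: tuple[SubstitutionRecord, ...]
    n_identical: int
    n_paired_columns: int            # columns whose species_a position is paired


@dataclass(frozen=True)
class ConservationVerdict:
    identity_fraction: float
    class_counts: dict[str, int]
    disruptive_fraction: float
    conserved: bool
    min_identity: float
    max_disruptive_fraction: float

    @property
    def verdict(self) -> str:
        return "yes" if self.conserved else "no"


def global_align(
    seq_a: RnaSequence,
    seq_b: RnaSequence,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -2.0,
) -> OrthologPair:
    """Optimal global alignment under linear scoring; deterministic
    (first alignment of the aligner's fixed traceback order)."""
    if len(seq_a) == 0 or len(seq_b) == 0:
        raise ValueError("cannot align empty sequences")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    alignment = aligner.align(seq_a.residues, seq_b.residues)[0]
    return OrthologPair(
        species_a=seq_a,
        species_b=seq_b,
        aligned_a=str(alignment[0]),
        aligned_b=str(alignment[1]),
        score=float(alignment.score),
    )


def _classify_column(
    res_a: str,
    res_b: str,
    partner_res_a: Optional[str],
    partner_res_b: Optional[str],
    paired: bool,
) -> str:
    """Classification rule for one substituted, non-gap column.

    The call is symmetric in the two species: a change is disruptive exactly
    when canonical pairing holds in one species but not the other.
    """
    if not paired:
        return "loop_located"
    if partner_res_b is None:
        return "disruptive"  # pairing partner deleted in the ortholog
    canonical_a = (res_a, partner_res_a) in CANONICAL_PAIRS
    canonical_b = (res_b, partner_res_b) in CANONICAL_PAIRS
    if canonical_a != canonical_b:
        return "disruptive"
    if canonical_b:
        if res_b != res_a and partner_res_b != partner_res_a:
            return "compensatory"
        return "wobble_preserving"
    # annotated as paired but non-canonical in both species: the local
    # mismatch is maintained, treat like an unpaired change
    return "loop_located"


def classify_substitutions(
    pair: OrthologPair, structure_a: RnaStructure
) -> list[SubstitutionRecord]:
    """Classify every non-identical alignment column.

    Gap columns are recorded as indels.  ``structure_a`` is given on
    species_a coordinates and must match its length.
    """
    if len(structure_a) != len(pair.species_a):
        raise ValueError(
            f"structure length {len(structure_a)} != species_a length "
            f"{len(pair.species_a)}"
        )
    pos_a = pair.positions_a()
    pos_b = pair.positions_b()
    col_of_a = {p: c for c, p in enumerate(pos_a) if p is not None}
    records = []
    for c, (ra, rb) in enumerate(zip(pair.aligned_a, pair.aligned_b)):
        if ra == rb:
            continue
        if ra == GAP or rb == GAP:
            klass = "indel"
        else:
            i = pos_a[c]
            j = structure_a.partner[i - 1]
            if j == 0:
                klass = _classify_column(ra, rb, None, None, paired=False)
            else:
                pcol = col_of_a[j]
                partner_res_a = pair.aligned_a[pcol]
                partner_res_b = pair.aligned_b[pcol]
                klass = _classify_column(
                    ra,
                    rb,
                    partner_res_a,
                    None if partner_res_b == GAP else partner_res_b,
                    paired=True,
                )
        records.append(
            SubstitutionRecord(
                column=c + 1,
                position_a=pos_a[c],
                position_b=pos_b[c],
                residue_a=ra,
                residue_b=rb,
                klass=klass,
            )
        )
    return records


def compare_orthologs(
    seq_a: RnaSequence,
    seq_b: RnaSequence,
    structure_a: RnaStructure,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -2.0,
) -> OrthologComparison:
    """Align two orthologs and classify all substitutions against the
    species_a structure."""
    pair = global_align(seq_a, seq_b, match=match, mismatch=mismatch, gap=gap)
    records = classify_substitutions(pair, structure_a)
    n_identical = sum(
        1 for ra, rb in zip(pair.aligned_a, pair.aligned_b) if ra == rb
    )
    n_paired = sum(
        1
        for p in pair.positions_a()
        if p is not None and structure_a.partner[p - 1] != 0
    )
    return OrthologComparison(
        pair=pair,
        records=tuple(records),
        n_identical=n_identical,
        n_paired_columns=n_paired,
    )


def verdict(
    comparison: OrthologComparison,
    min_identity: float = MIN_IDENTITY,
    max_disruptive_fraction: float = MAX_DISRUPTIVE_FRACTION,
    structure_a: Optional[RnaStructure] = None,
) -> ConservationVerdict:
    """Conservation call: identity and disruptive-fraction thresholds.

    Indels count against identity; an indel is additionally counted as
    disruptive only when it deletes a paired species_a position (requires
    ``structure_a``; without it indels are never disruptive).
    """
    counts = {k: 0 for k in CLASSES}
    for rec in comparison.records:
        counts[rec.klass] += 1
    identity = comparison.n_identical / comparison.pair.n_columns
    n_disruptive = counts["disruptive"]
    if structure_a is not None:
        for rec in comparison.records:
            if (
                rec.klass == "indel"
                and rec.position_a is not None
                and structure_a.partner[rec.position_a - 1] != 0
            ):
                n_disruptive += 1
    disruptive_fraction = (
        n_disruptive / comparison.n_paired_columns
        if comparison.n_paired_columns
        else 0.0
    )
    conserved = (
        identity >= min_identity
        and disruptive_fraction <= max_disruptive_fraction
    )
    return ConservationVerdict(
        identity_fraction=identity,
        class_counts=counts,
        disruptive_fraction=disruptive_fraction,
        conserved=conserved,
        min_identity=min_identity,
        max_disruptive_fraction=max_disruptive_fraction,
    )


def records_to_tsv(records: list[SubstitutionRecord]) -> str:
    rows = ["column\tposition_a\tposition_b\tresidue_a\tresidue_b\tclass"]
    for r in records:
        rows.append(
            f"{r.column}\t{r.position_a or ''}\t{r.position_b or ''}\t"
            f"{r.residue_a}\t{r.residue_b}\t{r.klass}"
        )
    return "\n".join(rows) + "\n"
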