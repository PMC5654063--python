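"""Synthetic substrates with the structural and statistical properties the
analysis assumes.

``make_barbell_sequence`` realizes a designed barbell — an edited stem and
an EIE stem separated by a large internal loop, closed by a terminal hairpin
— exactly: stem base-pair counts, interruption sizes, loop totals, the
transcript distance from the edit site to the EIE and its 5'/3' side are
all spec parameters recovered verbatim by the segmenter and the EIE scan.
Stems are GC-biased (~70% G-C pairs) so that base-pair-maximization folding
recovers at least the designed pair count without thermodynamic modelling.

``mutate_ortholog`` plants classifiable substitutions (compensatory,
wobble-preserving, loop, disruptive) at given per-position rates;
``simulate_peaks`` draws noisy A/G Sanger peak heights at a given true
editing fraction (multiplicative truncated-Gaussian noise — a documented
stand-in, as no noise model is published for peak heights);
``make_screen_cohort`` assembles a full screening cohort with a planted
EIE-by-efficiency contingency and its ground-truth table.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .eiescan import EditSite
from .rnastruct import (
    RnaSequence,
    RnaStructure,
    write_dotbracket,
    write_fasta,
)

GC_PAIR_FRACTION = 0.7
AU_PAIR_FRACTION = 0.2  # remainder is G-U wobble


class InfeasibleSpecError(ValueError):
    """A barbell spec whose geometry cannot be realized."""


@dataclass(frozen=True)
class BarbellSpec:
    """Design parameters for one barbell substrate.

    ``distance_nt`` is the number of nucleotides strictly between the edit
    site and the nearest EIE nucleotide; ``side`` says whether the EIE lies
    3' (downstream) or 5' (upstream) of the edit site.  Interruptions are
    (left, right) unpaired counts splitting a stem's helices; a one-sided
    interruption is a bulge, and two-sided interruptions must stay within
    the merge tolerance (total <= 4) so the stem remains one segment.
    ``eie_stem_bp = 0`` designs an EIE-deletion substrate (edited stem
    only).
    """

    edited_stem_bp: int = 28
    edited_stem_interruptions: tuple[tuple[int, int], ...] = ((1, 1), (1, 1))
    internal_loop: tuple[int, int] = (20, 15)
    eie_stem_bp: int = 43
    eie_interruptions: tuple[tuple[int, int], ...] = (
        (1, 1),
        (1, 1),
        (1, 1),
        (1, 1),
        (8, 0),
    )
    distance_nt: int = 45
    side: str = "3p"
    hairpin: int = 4
    leader: int = 5
    trailer: int = 5
    seed: int = 0
    substrate_id: str = "barbell"

    def __post_init__(self) -> None:
        if self.edited_stem_bp < 1:
            raise InfeasibleSpecError("edited stem needs at least 1 bp")
        if self.hairpin < 3:
            raise InfeasibleSpecError("hairpin loop must be >= 3 nt")
        if self.side not in ("5p", "3p"):
            raise InfeasibleSpecError("side must be '5p' or '3p'")
        if self.eie_stem_bp:
            left, right = self.internal_loop
            if left < 0 or right < 0 or left + right <= 6:
                raise InfeasibleSpecError(
                    "internal loop must total > 6 nt to separate the stems"
                )
        for stem_bp, interruptions in (
            (self.edited_stem_bp, self.edited_stem_interruptions),
            (self.eie_stem_bp, self.eie_interruptions),
        ):
            if stem_bp and len(interruptions) >= stem_bp:
                raise InfeasibleSpecError("more interruptions than helix chunks")
            for l, r in interruptions:
                if l < 0 or r < 0 or l + r == 0:
                    raise InfeasibleSpecError("empty interruption")
                if l > 0 and r > 0 and l + r > 4:
                    raise InfeasibleSpecError(
                        "two-sided interruption exceeds merge tolerance"
                    )


def _stem_strings(
    bp: int, interruptions: Sequence[tuple[int, int]]
) -> tuple[str, str]:
    """5' and 3' arm templates for a stem: '(' / ')' for pairs, '.' for
    interruption nucleotides.  Helices are split as evenly as possible."""
    k = len(interruptions) + 1
    base, extra = divmod(bp, k)
    chunks = [base + (1 if i < extra else 0) for i in range(k)]
    five = []
    three = []
    for i, c in enumerate(chunks):
        five.append("(" * c)
        three.append(")" * c)
        if i < len(interruptions):
            l, r = interruptions[i]
            five.append("." * l)
            three.append("." * r)
    return "".join(five), "".join(three[::-1])


def _template(spec: BarbellSpec) -> tuple[str, int]:
    """Dot-bracket template and 1-based edit position for a spec."""
    f1, t1 = _stem_strings(spec.edited_stem_bp, spec.edited_stem_interruptions)
    if spec.eie_stem_bp == 0:
        template = (
            "." * spec.leader + f1 + "." * spec.hairpin + t1 + "." * spec.trailer
        )
        # place the edit site at the central paired position of the 5' arm
        arm_start = spec.leader + 1
        paired = [i for i, ch in enumerate(f1) if ch == "("]
        edit_pos = arm_start + paired[len(paired) // 2]
        return template, edit_pos

    f2, t2 = _stem_strings(spec.eie_stem_bp, spec.eie_interruptions)
    loop_l, loop_r = spec.internal_loop
    template = (
        "." * spec.leader
        + f1
        + "." * loop_l
        + f2
        + "." * spec.hairpin
        + t2
        + "." * loop_r
        + t1
        + "." * spec.trailer
    )
    if spec.side == "3p":
        # edit site in the 5' arm of the edited stem, EIE begins after loop_l
        eie_start = spec.leader + len(f1) + loop_l + 1
        edit_pos = eie_start - spec.distance_nt - 1
        arm_lo, arm_hi = spec.leader + 1, spec.leader + len(f1)
    else:
        # edit site in the 3' arm, EIE ends before loop_r
        eie_end = spec.leader + len(f1) + loop_l + len(f2) + spec.hairpin + len(t2)
        edit_pos = eie_end + spec.distance_nt + 1
        arm_lo = eie_end + loop_r + 1
        arm_hi = arm_lo + len(t1) - 1
    if not arm_lo <= edit_pos <= arm_hi:
        raise InfeasibleSpecError(
            f"distance_nt={spec.distance_nt} places the edit site outside "
            f"the edited stem (needs {spec.side}-side loop <= distance <= "
            "loop + arm length - 1)"
        )
    if template[edit_pos - 1] == ".":
        raise InfeasibleSpecError(
            f"distance_nt={spec.distance_nt} places the edit site in a stem "
            "interruption; choose a distance landing on a paired position"
        )
    return template, edit_pos


def _pairs_from_template(template: str) -> list[tuple[int, int]]:
    stack: list[int] = []
    pairs = []
    for pos, ch in enumerate(template, start=1):
        if ch == "(":
            stack.append(pos)
        elif ch == ")":
            pairs.append((stack.pop(), pos))
    return pairs


def make_barbell_sequence(
    spec: BarbellSpec,
) -> tuple[RnaSequence, RnaStructure, EditSite]:
    """Realize a barbell spec as sequence + designed structure + edit site."""
    template, edit_pos = _template(spec)
    pairs = _pairs_from_template(template)
    rng = np.random.default_rng(spec.seed)
    residues = [""] * len(template)
    for i, j in pairs:
        if edit_pos in (i, j):
            a, b = ("A", "U") if i == edit_pos else ("U", "A")
        else:
            u = rng.random()
            if u < GC_PAIR_FRACTION:
                a, b = ("G", "C") if rng.random() < 0.5 else ("C", "G")
            elif u < GC_PAIR_FRACTION + AU_PAIR_FRACTION:
                a, b = ("A", "U") if rng.random() < 0.5 else ("U", "A")
            else:
                a, b = ("G", "U") if rng.random() < 0.5 else ("U", "G")
        residues[i - 1], residues[j - 1] = a, b
    for k, ch in enumerate(template):
        if ch == ".":
            residues[k] = "AC"[rng.integers(0, 2)]
    seq = RnaSequence(id=spec.substrate_id, residues="".join(residues))
    structure = RnaStructure.from_pairs(seq, pairs)
    site = EditSite(substrate_id=spec.substrate_id, position=edit_pos)
    return seq, structure, site


def random_barbell_spec(
    rng: np.random.Generator,
    with_eie: bool = True,
    substrate_id: str = "barbell",
) -> BarbellSpec:
    """Sample a feasible random barbell spec (geometry checked, the edit
    site guaranteed to land on a paired position)."""
    n_int = int(rng.integers(0, 3))
    edited_interruptions = tuple(
        (1, 1) if rng.random() < 0.6 else (int(rng.integers(1, 4)), 0)
        for _ in range(n_int)
    )
    edited_bp = int(rng.integers(8, 31))
    eie_bp = int(rng.integers(22, 51)) if with_eie else 0
    n_eint = int(rng.integers(0, 4)) if with_eie else 0
    eie_interruptions = tuple(
        (1, 1) if rng.random() < 0.5 else (int(rng.integers(1, 9)), 0)
        for _ in range(n_eint)
    )
    loop = (int(rng.integers(7, 25)), int(rng.integers(7, 25)))
    side = "3p" if rng.random() < 0.5 else "5p"
    f1, t1 = _stem_strings(edited_bp, edited_interruptions)
    arm = f1 if side == "3p" else t1
    adj_loop = loop[0] if side == "3p" else loop[1]
    # distances that land the edit site on a paired arm position
    if side == "3p":
        choices = [
            adj_loop + (len(arm) - 1 - k)
            for k, ch in enumerate(arm)
            if ch == "("
        ]
    else:
        choices = [adj_loop + k for k, ch in enumerate(arm) if ch == ")"]
    distance = int(rng.choice(choices)) if with_eie else 45
    return BarbellSpec(
        edited_stem_bp=edited_bp,
        edited_stem_interruptions=edited_interruptions,
        internal_loop=loop,
        eie_stem_bp=eie_bp,
        eie_interruptions=eie_interruptions,
        distance_nt=distance,
        side=side,
        hairpin=int(rng.integers(3, 9)),
        leader=int(rng.integers(3, 11)),
        trailer=int(rng.integers(3, 11)),
        seed=int(rng.integers(0, 2**31 - 1)),
        substrate_id=substrate_id,
    )


# ---------------------------------------------------------------------------
# Ortholog mutagenesis
# ---------------------------------------------------------------------------

_COMPENSATORY = {
    ("A", "U"): [("G", "C"), ("C", "G"), ("U", "A"), ("U", "G")],
    ("U", "A"): [("G", "C"), ("C", "G"), ("A", "U"), ("G", "U")],
    ("G", "C"): [("A", "U"), ("U", "A"), ("C", "G"), ("U", "G")],
    ("C", "G"): [("A", "U"), ("U", "A"), ("G", "C"), ("G", "U")],
    ("G", "U"): [("U", "A"), ("C", "G"), ("U", "G")],
    ("U", "G"): [("A", "U"), ("G", "C"), ("G", "U")],
}

_WOBBLE = {
    ("A", "U"): [("G", "U")],
    ("U", "A"): [("U", "G")],
    ("G", "C"): [("G", "U")],
    ("C", "G"): [("U", "G")],
    ("G", "U"): [("A", "U"), ("G", "C")],
    ("U", "G"): [("U", "A"), ("C", "G")],
}


def mutate_ortholog(
    sequence: RnaSequence,
    structure: RnaStructure,
    rate_compensatory: float = 0.0,
    rate_wobble: float = 0.0,
    rate_loop: float = 0.0,
    rate_disruptive: float = 0.0,
    seed: int = 0,
) -> RnaSequence:
    """Derive an ortholog by planting classifiable substitutions.

    The compensatory and wobble rates apply per base pair (they are
    inherently two-residue or partner-aware operations); the disruptive rate
    applies per paired position and the loop rate per unpaired position, so
    a disruptive rate r yields close to a fraction r of disrupted paired
    alignment columns.  At most one operation touches any pair.  With all
    rates zero the ortholog is identical.
    """
    from .rnastruct import CANONICAL_PAIRS

    rng = np.random.default_rng(seed)
    residues = list(sequence.residues)
    touched: set[int] = set()
    for i, j in structure.pairs():
        pair = (residues[i - 1], residues[j - 1])
        u = rng.random()
        if u < rate_compensatory:
            options = _COMPENSATORY[pair]
            # compensatory = both partners changed, pairing retained
            options = [
                (a, b) for a, b in options if a != pair[0] and b != pair[1]
            ]
            a, b = options[int(rng.integers(0, len(options)))]
            residues[i - 1], residues[j - 1] = a, b
            touched.update((i, j))
        elif u < rate_compensatory + rate_wobble:
            options = _WOBBLE[pair]
            a, b = options[int(rng.integers(0, len(options)))]
            residues[i - 1], residues[j - 1] = a, b
            touched.update((i, j))
    for pos in range(1, len(sequence) + 1):
        partner = structure.partner[pos - 1]
        if partner == 0 or pos in touched or partner in touched:
            continue
        if rng.random() < rate_disruptive:
            keep = residues[partner - 1]
            if pos < partner:
                bad = [
                    x for x in "ACGU"
                    if x != residues[pos - 1] and (x, keep) not in CANONICAL_PAIRS
                ]
            else:
                bad = [
                    x for x in "ACGU"
                    if x != residues[pos - 1] and (keep, x) not in CANONICAL_PAIRS
                ]
            residues[pos - 1] = bad[int(rng.integers(0, len(bad)))]
            touched.add(pos)
    for pos in range(1, len(sequence) + 1):
        if structure.partner[pos - 1] == 0 and rng.random() < rate_loop:
            others = [x for x in "ACGU" if x != residues[pos - 1]]
            residues[pos - 1] = others[int(rng.integers(0, 3))]
    return RnaSequence(
        id=sequence.id + "_ortholog", residues="".join(residues)
    )


# ---------------------------------------------------------------------------
# Sanger peak-height simulation
# ---------------------------------------------------------------------------

def simulate_peaks(
    true_fraction: float,
    base_height: float = 1000.0,
    noise_sd: float = 0.05,
    n_replicates: int = 3,
    seed: int = 0,
    substrate_id: str = "sim",
    offset: int = 0,
):
    """Noisy A/G peak heights at a true editing fraction f.

    Heights are A = H*(1-f)*(1+eps), G = H*f*(1+eps') with eps ~
    Normal(0, noise_sd^2) truncated at -0.9, independently per peak.
    """
    from .editquant import PeakRecord  # local import avoids a cycle

    if not 0.0 <= true_fraction <= 1.0:
        raise ValueError("true_fraction must be in [0, 1]")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    records = []
    for rep in range(1, n_replicates + 1):
        eps = np.maximum(rng.normal(0.0, noise_sd, size=2), -0.9) if noise_sd else np.zeros(2)
        height_a = base_height * (1.0 - true_fraction) * (1.0 + eps[0])
        height_g = base_height * true_fraction * (1.0 + eps[1])
        records.append(
            PeakRecord(
                substrate_id=substrate_id,
                offset=offset,
                replicate=rep,
                height_A=float(height_a),
                height_G=float(height_g),
            )
        )
    return records


# ---------------------------------------------------------------------------
# Screening cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScreenCohortSpec:
    """A planted EIE-by-efficiency contingency: class sizes, how many of
    each class carry an EIE, the editing ranges per class, and peak noise."""

    n_high: int = 11
    n_high_with_eie: int = 10
    n_low: int = 12
    n_low_with_eie: int = 1
    high_range: tuple[float, float] = (50.0, 100.0)
    low_range: tuple[float, float] = (1.0, 45.0)
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_high_with_eie > self.n_high or self.n_low_with_eie > self.n_low:
            raise ValueError("with-EIE counts cannot exceed class sizes")


@dataclass(frozen=True)
class CohortSubstrate:
    substrate_id: str
    sequence: RnaSequence
    structure: RnaStructure
    edit_site: EditSite
    editing_percent: float
    ortholog: Optional[RnaSequence]
    has_eie: bool


@dataclass(frozen=True)
class Cohort:
    substrates: tuple[CohortSubstrate, ...]
    truth: pd.DataFrame

    def write(self, outdir: str) -> None:
        """Emit FASTA, dot-bracket structures, the substrate table and the
        truth table into a directory."""
        os.makedirs(outdir, exist_ok=True)
        with open(os.path.join(outdir, "substrates.fasta"), "w") as fh:
            fh.write(write_fasta([s.sequence for s in self.substrates]))
        with open(os.path.join(outdir, "orthologs.fasta"), "w") as fh:
            fh.write(
                write_fasta(
                    [s.ortholog for s in self.substrates if s.ortholog is not None]
                )
            )
        with open(os.path.join(outdir, "structures.dbn"), "w") as fh:
            for s in self.substrates:
                fh.write(write_dotbracket(s.structure))
        rows = []
        for s in self.substrates:
            rows.append(
                {
                    "substrate_id": s.substrate_id,
                    "edit_position": s.edit_site.position,
                    "editing_percent": s.editing_percent,
                    "has_ortholog": int(s.ortholog is not None),
                }
            )
        pd.DataFrame(rows).to_csv(
            os.path.join(outdir, "substrates.tsv"), sep="\t", index=False
        )
        self.truth.to_csv(
            os.path.join(outdir, "truth.tsv"), sep="\t", index=False
        )


def make_screen_cohort(spec: ScreenCohortSpec) -> Cohort:
    """Generate a cohort realizing the planted contingency exactly.

    Substrates with a planted EIE get a conserved ortholog (compensatory and
    loop substitutions only); substrates without one carry, at most, a decoy
    flanking stem below the EIE base-pair threshold and no ortholog.
    """
    rng = np.random.default_rng(spec.seed)
    substrates = []
    truth_rows = []

    def build(idx: int, klass: str, with_eie: bool, lo: float, hi: float) -> None:
        sid = f"{klass}_{idx:02d}"
        bspec = random_barbell_spec(rng, with_eie=with_eie, substrate_id=sid)
        if not with_eie and rng.random() < 0.5:
            # decoy flanking stem, too short to qualify as an EIE
            decoy_bp = int(rng.integers(5, 12))
            f1, _ = _stem_strings(
                bspec.edited_stem_bp, bspec.edited_stem_interruptions
            )
            dchoices = [
                7 + (len(f1) - 1 - k) for k, ch in enumerate(f1) if ch == "("
            ]
            bspec = replace(
                bspec,
                eie_stem_bp=decoy_bp,
                eie_interruptions=(),
                internal_loop=(7, 7),
                side="3p",
                distance_nt=int(rng.choice(dchoices)),
            )
        seq, structure, site = make_barbell_sequence(bspec)
        percent = float(np.round(rng.uniform(lo, hi), 1))
        ortholog = None
        if with_eie:
            ortholog = mutate_ortholog(
                seq,
                structure,
                rate_compensatory=0.03,
                rate_loop=0.05,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        substrates.append(
            CohortSubstrate(
                substrate_id=sid,
                sequence=seq,
                structure=structure,
                edit_site=site,
                editing_percent=percent,
                ortholog=ortholog,
                has_eie=with_eie,
            )
        )
        truth_rows.append(
            {"substrate_id": sid, "class": klass, "has_eie": int(with_eie)}
        )

    for i in range(spec.n_high):
        build(i, "high", i < spec.n_high_with_eie, *spec.high_range)
    for i in range(spec.n_low):
        build(i, "low", i < spec.n_low_with_eie, *spec.low_range)
    return Cohort(substrates=tuple(substrates), truth=pd.DataFrame(truth_rows))
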