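"""Orchestration of the full EIE screen.

A screen takes a table of substrates (sequence, structure or fold request,
edit position, measured editing percent, optional ortholog), produces one
:class:`~eiescreen.eiescan.EieReport` per substrate and summarizes the
EIE-by-efficiency contingency: how many high-efficiency (>= 50%) and
low-efficiency (<= 45%) sites carry a conserved, stable adjacent stem.

Three input routes share this machinery: a substrate TSV pointing at FASTA
and structure files, an in-memory synthetic cohort, and the packaged
transcription of the published survey of 23 conserved site-selective
editing substrates (used as a fixture: its conserved/stable calls and
metrics are inputs, the contingency counts are recomputed from them).
"""

from __future__ import annotations

import importlib.resources
import json
import logging
import os
from dataclasses import asdict, dataclass, field
from typing import Optional, Sequence

import pandas as pd
import yaml

from . import conservation, eiescan, rnastruct, segmenter
from .eiescan import EditSite, EieReport
from .rnastruct import RnaSequence, RnaStructure
from .synthdata import Cohort

logger = logging.getLogger("eiescreen")


@dataclass(frozen=True)
class ScreenParams:
    """All tunable thresholds of the screen, overridable from a YAML/JSON
    config file and from CLI flags."""

    merge_tolerance: int = segmenter.MERGE_TOLERANCE
    helix_end_threshold: int = segmenter.HELIX_END_THRESHOLD
    merge_bulges: bool = True
    min_bp: int = eiescan.MIN_EIE_BP
    min_paired_fraction: float = eiescan.MIN_PAIRED_FRACTION
    min_identity: float = conservation.MIN_IDENTITY
    max_disruptive_fraction: float = conservation.MAX_DISRUPTIVE_FRACTION
    min_hairpin: int = rnastruct.MIN_HAIRPIN
    allow_gu: bool = True
    stacking_bonus: float = 0.5

    @classmethod
    def from_config(cls, path: str, **overrides) -> "ScreenParams":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)


@dataclass(frozen=True)
class ScreenSummary:
    """Contingency counts plus the per-substrate reports."""

    n_substrates: int
    n_high: int
    n_low: int
    n_unclassified: int
    n_high_with_conserved_stable_stem: int
    n_low_with_conserved_stable_stem: int
    reports: tuple[EieReport, ...]

    def __post_init__(self) -> None:
        # count identities are structural invariants, not test-only checks
        assert self.n_substrates == self.n_high + self.n_low + self.n_unclassified
        assert self.n_high_with_conserved_stable_stem <= self.n_high
        assert self.n_low_with_conserved_stable_stem <= self.n_low

    @classmethod
    def from_reports(cls, reports: Sequence[EieReport]) -> "ScreenSummary":
        n_high = sum(1 for r in reports if r.efficiency_class == "high")
        n_low = sum(1 for r in reports if r.efficiency_class == "low")
        n_uncl = sum(1 for r in reports if r.efficiency_class == "unclassified")

        def with_stem(klass: str) -> int:
            return sum(
                1
                for r in reports
                if r.efficiency_class == klass
                and r.conserved_adjacent_stem == "yes"
                and r.stable_adjacent_stem == "yes"
            )

        return cls(
            n_substrates=len(reports),
            n_high=n_high,
            n_low=n_low,
            n_unclassified=n_uncl,
            n_high_with_conserved_stable_stem=with_stem("high"),
            n_low_with_conserved_stable_stem=with_stem("low"),
            reports=tuple(reports),
        )

    def counts(self) -> dict[str, int]:
        return {
            "n_substrates": self.n_substrates,
            "n_high": self.n_high,
            "n_low": self.n_low,
            "n_unclassified": self.n_unclassified,
            "n_high_with_conserved_stable_stem": self.n_high_with_conserved_stable_stem,
            "n_low_with_conserved_stable_stem": self.n_low_with_conserved_stable_stem,
        }


# ---------------------------------------------------------------------------
# Screening a substrate, shared by all routes
# ---------------------------------------------------------------------------

def screen_substrate(
    substrate_id: str,
    structure: RnaStructure,
    edit_site: EditSite,
    editing_percent: float,
    ortholog: Optional[RnaSequence] = None,
    params: ScreenParams = ScreenParams(),
    structure_source: str = "given",
) -> EieReport:
    """Segment, scan for EIE candidates, assess conservation, build a row."""
    segmented = segmenter.segment(
        structure,
        merge_tolerance=params.merge_tolerance,
        helix_end_threshold=params.helix_end_threshold,
        merge_bulges=params.merge_bulges,
    )
    conserved: Optional[str] = None
    if ortholog is not None:
        comparison = conservation.compare_orthologs(
            structure.sequence, ortholog, structure
        )
        v = conservation.verdict(
            comparison,
            min_identity=params.min_identity,
            max_disruptive_fraction=params.max_disruptive_fraction,
            structure_a=structure,
        )
        conserved = v.verdict
    return eiescan.build_report(
        substrate_id=substrate_id,
        segmented=segmented,
        edit_site=edit_site,
        editing_percent=editing_percent,
        conservation_verdict=conserved,
        min_bp=params.min_bp,
        min_paired_fraction=params.min_paired_fraction,
        structure_source=structure_source,
    )


def screen_cohort(cohort: Cohort, params: ScreenParams = ScreenParams()) -> ScreenSummary:
    """Run the screen over an in-memory (synthetic) cohort."""
    reports = [
        screen_substrate(
            s.substrate_id,
            s.structure,
            s.edit_site,
            s.editing_percent,
            ortholog=s.ortholog,
            params=params,
        )
        for s in cohort.substrates
    ]
    return ScreenSummary.from_reports(reports)


# ---------------------------------------------------------------------------
# File-based screen
# ---------------------------------------------------------------------------

SUBSTRATE_COLUMNS = [
    "substrate_id",
    "fasta",
    "structure",
    "edit_position",
    "editing_percent",
]  # optional: ortholog_fasta


def _load_structure(path_or_fold: str, sequence: RnaSequence, params: ScreenParams):
    if path_or_fold == "fold":
        return (
            rnastruct.fold(
                sequence,
                min_hairpin=params.min_hairpin,
                allow_gu=params.allow_gu,
                stacking_bonus=params.stacking_bonus,
            ),
            "folded",
        )
    with open(path_or_fold) as fh:
        if path_or_fold.endswith(".ct"):
            structure = rnastruct.parse_ct(fh)
        else:
            structure = rnastruct.read_dotbracket(fh)[0]
    if structure.sequence.residues != sequence.residues:
        raise ValueError(
            f"structure file {path_or_fold} does not match the FASTA sequence"
        )
    return structure, "given"


def run_screen(
    substrate_table: pd.DataFrame, params: ScreenParams = ScreenParams(),
    base_dir: str = ".",
) -> ScreenSummary:
    """Screen substrates described by a table of file references.

    Unreadable rows are logged and reported as not-determined (efficiency
    still classified from the measured percent) rather than dropped.
    """
    missing = set(SUBSTRATE_COLUMNS) - set(substrate_table.columns)
    if missing:
        raise ValueError(f"substrate table missing columns: {sorted(missing)}")
    reports = []
    for row in substrate_table.itertuples():
        sid = str(row.substrate_id)
        percent = float(row.editing_percent)
        try:
            fasta_path = os.path.join(base_dir, str(row.fasta))
            with open(fasta_path) as fh:
                seqs = {s.id: s for s in rnastruct.parse_fasta(fh)}
            sequence = seqs.get(sid) or next(iter(seqs.values()))
            structure_ref = str(row.structure)
            if structure_ref != "fold":
                structure_ref = os.path.join(base_dir, structure_ref)
            structure, source = _load_structure(structure_ref, sequence, params)
            ortholog = None
            ortho_path = getattr(row, "ortholog_fasta", None)
            if isinstance(ortho_path, str) and ortho_path and ortho_path != "nan":
                with open(os.path.join(base_dir, ortho_path)) as fh:
                    ortholog = rnastruct.parse_fasta(fh)[0]
            site = EditSite(substrate_id=sid, position=int(row.edit_position))
            reports.append(
                screen_substrate(
                    sid, structure, site, percent,
                    ortholog=ortholog, params=params, structure_source=source,
                )
            )
        except (OSError, ValueError, rnastruct.StructureError) as exc:
            logger.error("substrate %s unreadable: %s", sid, exc)
            reports.append(
                EieReport(
                    substrate_id=sid,
                    edit_site=EditSite(substrate_id=sid, position=1),
                    editing_percent=percent,
                    efficiency_class=eiescan.classify_efficiency(percent),
                    conserved_adjacent_stem="not_determined",
                    stable_adjacent_stem="not_determined",
                    candidates=(),
                    structure_source="error",
                )
            )
    return ScreenSummary.from_reports(reports)


# ---------------------------------------------------------------------------
# Packaged survey transcription
# ---------------------------------------------------------------------------

def load_survey() -> pd.DataFrame:
    """The packaged transcription of the published 23-substrate survey."""
    ref = importlib.resources.files("eiescreen.data").joinpath(
        "conserved_editing_survey.tsv"
    )
    with ref.open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#")


def screen_survey(survey: Optional[pd.DataFrame] = None) -> ScreenSummary:
    """Recompute the screening contingency from the survey transcription.

    The transcription's per-substrate conserved/stable calls and EIE metrics
    are inputs; efficiency classes and all counts are recomputed.
    """
    if survey is None:
        survey = load_survey()
    reports = []
    for row in survey.itertuples():
        conserved = str(row.conserved_adjacent_stem).lower()
        stable = str(row.stable_adjacent_stem).lower()
        reports.append(
            EieReport(
                substrate_id=f"{row.substrate}_{row.edit_site}",
                edit_site=EditSite(
                    substrate_id=str(row.substrate),
                    position=1,
                    amino_acid_change=str(row.edit_site),
                ),
                editing_percent=float(row.percent_editing),
                efficiency_class=eiescan.classify_efficiency(
                    float(row.percent_editing)
                ),
                conserved_adjacent_stem=(
                    conserved if conserved in ("yes", "no") else "not_determined"
                ),
                stable_adjacent_stem=(
                    stable if stable in ("yes", "no") else "not_determined"
                ),
                candidates=(),
                structure_source="survey",
            )
        )
    return ScreenSummary.from_reports(reports)


# ---------------------------------------------------------------------------
# Output
# ---------------------------------------------------------------------------

def summary_to_tsv(summary: ScreenSummary) -> str:
    """Per-substrate TSV mirroring the survey columns plus candidates."""
    rows = [
        "substrate_id\tedit_site\tediting_percent\tefficiency_class\t"
        "conserved_adjacent_stem\tstable_adjacent_stem\t"
        "eie_length_nt\teie_bp\teie_distance_nt\teie_side\tstructure_source"
    ]
    for r in summary.reports:
        aa = r.edit_site.amino_acid_change or str(r.edit_site.position)
        if r.candidates:
            lengths = ",".join(str(c.length_nt) for c in r.candidates)
            bps = ",".join(str(c.bp_count) for c in r.candidates)
            dists = ",".join(str(c.distance_nt) for c in r.candidates)
            sides = ",".join(c.side for c in r.candidates)
        else:
            lengths = bps = dists = sides = "ND"
        rows.append(
            f"{r.substrate_id}\t{aa}\t{r.editing_percent:g}\t"
            f"{r.efficiency_class}\t{r.conserved_adjacent_stem}\t"
            f"{r.stable_adjacent_stem}\t{lengths}\t{bps}\t{dists}\t{sides}\t"
            f"{r.structure_source}"
        )
    return "\n".join(rows) + "\n"


def summary_to_json(summary: ScreenSummary) -> str:
    payload = {"counts": summary.counts(), "substrates": []}
    for r in summary.reports:
        payload["substrates"].append(
            {
                "substrate_id": r.substrate_id,
                "edit_position": r.edit_site.position,
                "amino_acid_change": r.edit_site.amino_acid_change,
                "editing_percent": r.editing_percent,
                "efficiency_class": r.efficiency_class,
                "conserved_adjacent_stem": r.conserved_adjacent_stem,
                "stable_adjacent_stem": r.stable_adjacent_stem,
                "structure_source": r.structure_source,
                "candidates": [
                    {
                        "side": c.side,
                        "length_nt": c.length_nt,
                        "bp_count": c.bp_count,
                        "distance_nt": c.distance_nt,
                        "stable": c.stable,
                    }
                    for c in r.candidates
                ],
            }
        )
    return json.dumps(payload, indent=2, sort_keys=True) + "\n"
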