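"""Generators: design recovery, planted mutations, peak noise, cohorts."""

import numpy as np
import pytest

from eiescreen import (
    BarbellSpec,
    InfeasibleSpecError,
    ScreenCohortSpec,
    compare_orthologs,
    find_eie_candidates,
    identify_edited_stem,
    make_barbell_sequence,
    make_screen_cohort,
    mutate_ortholog,
    percent_editing,
    random_barbell_spec,
    simulate_peaks,
    summarize,
    verdict,
)
from eiescreen.rnastruct import fold
from eiescreen.segmenter import segment


class TestBarbellGenerator:
    def test_determinism(self):
        a = make_barbell_sequence(BarbellSpec(seed=5))
        b = make_barbell_sequence(BarbellSpec(seed=5))
        assert a[0].residues == b[0].residues
        assert a[1].pairs() == b[1].pairs()
        assert a[2] == b[2]

    def test_infeasible_specs_rejected(self):
        with pytest.raises(InfeasibleSpecError):
            BarbellSpec(hairpin=2)
        with pytest.raises(InfeasibleSpecError):
            BarbellSpec(internal_loop=(2, 2))  # too small to separate stems
        with pytest.raises(InfeasibleSpecError):
            BarbellSpec(edited_stem_interruptions=((3, 3),))  # 6 > tolerance
        with pytest.raises(InfeasibleSpecError):
            make_barbell_sequence(BarbellSpec(distance_nt=1000))

    def test_delta_eie_substrate(self):
        _, structure, site = make_barbell_sequence(BarbellSpec(eie_stem_bp=0))
        seg = segment(structure)
        assert len(seg.stems()) == 1
        assert find_eie_candidates(seg, site) == []

    @pytest.mark.parametrize("trial", range(25))
    def test_generator_analyzer_roundtrip_exact(self, trial):
        """Segmentation and the EIE scan recover every design parameter of a
        random barbell spec exactly."""
        rng = np.random.default_rng(1000 + trial)
        spec = random_barbell_spec(rng, substrate_id=f"rt{trial}")
        _, structure, site = make_barbell_sequence(spec)
        seg = segment(structure)
        assert identify_edited_stem(seg, site).bp_count == spec.edited_stem_bp
        (cand,) = find_eie_candidates(seg, site)
        assert cand.bp_count == spec.eie_stem_bp
        assert cand.distance_nt == spec.distance_nt
        assert cand.side == spec.side
        loops = seg.internal_loops()
        assert loops[0].total == sum(spec.internal_loop)

    def test_fold_recovers_at_least_designed_pairs(self):
        # small substrate keeps the cubic-time folder fast
        spec = BarbellSpec(
            edited_stem_bp=10,
            edited_stem_interruptions=(),
            eie_stem_bp=22,
            eie_interruptions=((1, 1),),
            internal_loop=(8, 8),
            distance_nt=12,
            leader=3,
            trailer=3,
            seed=6,
        )
        _, structure, _ = make_barbell_sequence(spec)
        folded = fold(structure.sequence)
        assert folded.pair_count() >= structure.pair_count()


def test_thermodynamic_folding_cross_check():
    """Independent cross-check: a thermodynamic MFE folder applied to the
    designed sequence reproduces the barbell architecture — the same edited
    stem and a single downstream EIE candidate with metrics within a couple
    of nucleotides of the design (MFE structures may shift a closing pair)."""
    RNA = pytest.importorskip("RNA")
    spec = BarbellSpec(substrate_id="x", seed=1)
    seq, _, site = make_barbell_sequence(spec)
    db, _ = RNA.fold(seq.residues)
    from eiescreen import parse_dotbracket

    seg = segment(parse_dotbracket(seq.residues, db))
    edited = identify_edited_stem(seg, site)
    assert abs(edited.bp_count - spec.edited_stem_bp) <= 2
    (cand,) = find_eie_candidates(seg, site)
    assert cand.side == "3p"
    assert abs(cand.bp_count - spec.eie_stem_bp) <= 2
    assert abs(cand.distance_nt - spec.distance_nt) <= 6


class TestOrthologGenerator:
    def test_zero_rates_identity(self):
        seq, structure, _ = make_barbell_sequence(BarbellSpec(seed=3))
        assert mutate_ortholog(seq, structure, seed=1).residues == seq.residues

    def test_compensatory_only_never_disruptive(self):
        seq, structure, _ = make_barbell_sequence(BarbellSpec(seed=3))
        ortho = mutate_ortholog(seq, structure, rate_compensatory=0.1, seed=1)
        comparison = compare_orthologs(seq, ortho, structure)
        classes = {r.klass for r in comparison.records}
        assert classes <= {"compensatory"}
        assert len(comparison.records) > 0
        assert verdict(comparison, structure_a=structure).conserved

    def test_disruptive_rate_breaks_conservation(self):
        seq, structure, _ = make_barbell_sequence(BarbellSpec(seed=3))
        ortho = mutate_ortholog(seq, structure, rate_disruptive=0.15, seed=1)
        comparison = compare_orthologs(seq, ortho, structure)
        assert not verdict(comparison, structure_a=structure).conserved

    def test_wobble_and_loop_classes_recovered(self):
        seq, structure, _ = make_barbell_sequence(BarbellSpec(seed=3))
        ortho = mutate_ortholog(
            seq, structure, rate_wobble=0.2, rate_loop=0.3, seed=4
        )
        classes = {
            r.klass for r in compare_orthologs(seq, ortho, structure).records
        }
        assert classes <= {"wobble_preserving", "loop_located"}
        assert classes == {"wobble_preserving", "loop_located"}


class TestPeakSimulator:
    def test_noise_free_arithmetic(self):
        (rec,) = simulate_peaks(0.66, base_height=1000, noise_sd=0.0, n_replicates=1)
        assert rec.height_A == pytest.approx(340.0)
        assert rec.height_G == pytest.approx(660.0)
        assert percent_editing(rec.height_A, rec.height_G) == pytest.approx(66.0)

    def test_unedited_site(self):
        records = simulate_peaks(0.0, noise_sd=0.05, n_replicates=5, seed=2)
        assert all(r.height_G == 0.0 for r in records)
        (m,) = summarize(records)
        assert m.mean == 0.0

    def test_determinism(self):
        a = simulate_peaks(0.4, noise_sd=0.1, n_replicates=4, seed=9)
        b = simulate_peaks(0.4, noise_sd=0.1, n_replicates=4, seed=9)
        assert a == b

    def test_estimator_recovery(self):
        """Mean of the peak-ratio estimator converges to the true editing
        fraction; at n=200 the error stays within 3*sigma*100/sqrt(n)."""
        records = simulate_peaks(0.66, noise_sd=0.05, n_replicates=200, seed=11)
        (m,) = summarize(records)
        tolerance = 3 * 0.05 * 100 / np.sqrt(200)
        assert abs(m.mean - 66.0) < tolerance


class TestCohorts:
    def test_planted_contingency_recovered(self):
        from eiescreen import screen_cohort

        cohort = make_screen_cohort(ScreenCohortSpec(seed=21))
        summary = screen_cohort(cohort)
        assert summary.counts() == {
            "n_substrates": 23,
            "n_high": 11,
            "n_low": 12,
            "n_unclassified": 0,
            "n_high_with_conserved_stable_stem": 10,
            "n_low_with_conserved_stable_stem": 1,
        }
        # detection agrees with the truth table substrate by substrate
        truth = dict(zip(cohort.truth.substrate_id, cohort.truth.has_eie))
        for report in summary.reports:
            assert report.has_eie == bool(truth[report.substrate_id])

    def test_all_with_eie_sensitivity_one(self):
        from eiescreen import screen_cohort

        cohort = make_screen_cohort(
            ScreenCohortSpec(n_high=5, n_high_with_eie=5, n_low=0, n_low_with_eie=0, seed=2)
        )
        summary = screen_cohort(cohort)
        assert all(r.has_eie for r in summary.reports)

    def test_empty_cohort(self):
        from eiescreen import screen_cohort

        cohort = make_screen_cohort(
            ScreenCohortSpec(n_high=0, n_high_with_eie=0, n_low=0, n_low_with_eie=0)
        )
        summary = screen_cohort(cohort)
        assert summary.n_substrates == 0

    def test_invalid_contingency(self):
        with pytest.raises(ValueError):
            ScreenCohortSpec(n_high=2, n_high_with_eie=3)

    def test_cohort_write_reads_back(self, tmp_path):
        cohort = make_screen_cohort(
            ScreenCohortSpec(n_high=2, n_high_with_eie=2, n_low=2, n_low_with_eie=0, seed=5)
        )
        cohort.write(str(tmp_path))
        for name in ("substrates.fasta", "structures.dbn", "substrates.tsv", "truth.tsv"):
            assert (tmp_path / name).exists()
        from eiescreen import parse_fasta, read_dotbracket

        seqs = parse_fasta((tmp_path / "substrates.fasta").read_text())
        structs = read_dotbracket((tmp_path / "structures.dbn").read_text())
        assert len(seqs) == len(structs) == 4
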