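"""EIE candidate detection, stability and efficiency classification."""

import numpy as np
import pytest

from eiescreen import (
    BarbellSpec,
    EditSite,
    UnpairedEditSiteError,
    build_report,
    classify_efficiency,
    find_eie_candidates,
    identify_edited_stem,
    make_barbell_sequence,
    random_barbell_spec,
    stability_check,
)
from eiescreen.rnastruct import mirror, parse_dotbracket
from eiescreen.segmenter import segment


class TestIdentifyEditedStem:
    def test_barbell_edit_site_in_short_stem(self, glua2_fixture):
        _, _, structure, site = glua2_fixture
        stem = identify_edited_stem(segment(structure), site)
        assert stem.bp_count == 28

    def test_single_hairpin(self):
        s = parse_dotbracket("GGGGGAAACCCCC", "(((((...)))))")
        site = EditSite("kv", position=3)
        assert identify_edited_stem(segment(s), site).bp_count == 5

    def test_site_in_internal_loop_errors(self, glua2_fixture):
        spec, _, structure, site = glua2_fixture
        # first nucleotide of the 20-nt loop half, right after the 5' arm
        loop_pos = site.position + spec.distance_nt - spec.internal_loop[0] + 1
        seg = segment(structure)
        with pytest.raises(UnpairedEditSiteError, match="not within any stem"):
            identify_edited_stem(seg, EditSite("x", position=loop_pos))


class TestFindCandidates:
    def test_barbell_one_downstream_candidate(self, glua2_fixture):
        _, _, structure, site = glua2_fixture
        (cand,) = find_eie_candidates(segment(structure), site)
        assert cand.bp_count == 43
        assert cand.length_nt == 102
        assert cand.distance_nt == 45
        assert cand.side == "3p"

    def test_deleted_eie_yields_none(self):
        spec = BarbellSpec(eie_stem_bp=0, substrate_id="delta_eie")
        _, structure, site = make_barbell_sequence(spec)
        assert find_eie_candidates(segment(structure), site) == []

    def test_upstream_relocation_flips_side_only(self):
        base = BarbellSpec(substrate_id="us", side="3p", seed=5)
        up = BarbellSpec(
            substrate_id="us", side="5p", distance_nt=50,
            internal_loop=(20, 21), seed=5,
        )
        for spec, side, dist in ((base, "3p", 45), (up, "5p", 50)):
            _, structure, site = make_barbell_sequence(spec)
            (cand,) = find_eie_candidates(segment(structure), site)
            assert (cand.side, cand.distance_nt) == (side, dist)
            assert cand.bp_count == 43

    def test_min_bp_excludes_short_stems(self, glua2_fixture):
        _, _, structure, site = glua2_fixture
        assert find_eie_candidates(segment(structure), site, min_bp=44) == []

    def test_mirror_invariance(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            spec = random_barbell_spec(rng)
            _, structure, site = make_barbell_sequence(spec)
            (c,) = find_eie_candidates(segment(structure), site)
            m_site = EditSite(site.substrate_id, len(structure) + 1 - site.position)
            (cm,) = find_eie_candidates(segment(mirror(structure)), m_site)
            assert cm.side != c.side
            assert (cm.length_nt, cm.bp_count, cm.distance_nt) == (
                c.length_nt,
                c.bp_count,
                c.distance_nt,
            )

    def test_distance_additivity(self):
        """Widening the loop between the stems by k nt adds exactly k to the
        distance and changes no other candidate metric."""
        for k in (1, 5, 12):
            a = BarbellSpec(seed=2)
            b = BarbellSpec(
                seed=2,
                internal_loop=(a.internal_loop[0] + k, a.internal_loop[1]),
                distance_nt=a.distance_nt + k,
            )
            _, sa, ea = make_barbell_sequence(a)
            _, sb, eb = make_barbell_sequence(b)
            (ca,) = find_eie_candidates(segment(sa), ea)
            (cb,) = find_eie_candidates(segment(sb), eb)
            assert cb.distance_nt == ca.distance_nt + k
            assert (cb.bp_count, cb.length_nt, cb.side) == (
                ca.bp_count,
                ca.length_nt,
                ca.side,
            )


class TestStability:
    def test_long_mostly_paired_stem_is_stable(self, glua2_fixture):
        _, _, structure, site = glua2_fixture
        (cand,) = find_eie_candidates(segment(structure), site)
        assert cand.stem.paired_fraction == pytest.approx(2 * 43 / 102)
        assert stability_check(cand)

    def test_short_perfect_helix_not_stable(self):
        spec = BarbellSpec(
            eie_stem_bp=8, eie_interruptions=(), distance_nt=25, seed=4
        )
        _, structure, site = make_barbell_sequence(spec)
        (cand,) = find_eie_candidates(segment(structure), site, min_bp=1)
        assert cand.bp_count == 8
        assert not stability_check(cand)  # 8 < 20 bp

    def test_sparse_stem_not_stable(self):
        # 22 bp spread over 78 nt: paired fraction 0.56 < 0.6
        spec = BarbellSpec(
            eie_stem_bp=22,
            eie_interruptions=(
                (4, 0), (4, 0), (4, 0), (4, 0), (4, 0), (4, 0), (4, 0),
                (3, 0), (3, 0),
            ),
            distance_nt=25,
            seed=4,
        )
        _, structure, site = make_barbell_sequence(spec)
        (cand,) = find_eie_candidates(segment(structure), site)
        assert cand.stem.paired_fraction < 0.6
        assert not stability_check(cand)


class TestEfficiencyClasses:
    @pytest.mark.parametrize(
        "percent,klass",
        [(100, "high"), (50, "high"), (72, "high"),
         (45, "low"), (25, "low"), (1, "low"), (0, "low"),
         (47, "unclassified"), (49.9, "unclassified")],
    )
    def test_thresholds(self, percent, klass):
        assert classify_efficiency(percent) == klass

    @pytest.mark.parametrize("bad", [-1, 101, 150.0])
    def test_out_of_range(self, bad):
        with pytest.raises(ValueError):
            classify_efficiency(bad)


class TestBuildReport:
    def test_full_row(self, glua2_fixture):
        _, _, structure, site = glua2_fixture
        report = build_report(
            "GluA2_QR", segment(structure), site, 100.0,
            conservation_verdict="yes",
        )
        assert report.efficiency_class == "high"
        assert report.conserved_adjacent_stem == "yes"
        assert report.stable_adjacent_stem == "yes"
        assert len(report.candidates) == 1
        assert report.candidates[0].stable

    def test_no_flanking_stem(self):
        spec = BarbellSpec(eie_stem_bp=0)
        _, structure, site = make_barbell_sequence(spec)
        report = build_report("flat", segment(structure), site, 10.0)
        assert report.efficiency_class == "low"
        assert report.candidates == ()
        assert report.stable_adjacent_stem == "not_determined"
        assert report.conserved_adjacent_stem == "not_determined"

    def test_two_flanking_stems_both_sides(self):
        """A substrate with stems on both sides of the edited stem, as in
        kainate-receptor-type substrates, yields two candidates."""
        # edited stem nested between an outer (enclosing) stem and an inner one
        db_seq = (
            "G" * 22 + "A" * 10 + "G" * 24 + "A" * 10 + "G" * 25
            + "AAAA" + "C" * 25 + "A" * 12 + "C" * 24 + "A" * 10 + "C" * 22
        )
        db = (
            "(" * 22 + "." * 10 + "(" * 24 + "." * 10 + "(" * 25
            + "...." + ")" * 25 + "." * 12 + ")" * 24 + "." * 10 + ")" * 22
        )
        structure = parse_dotbracket(db_seq, db)
        site = EditSite("gluk2_like", position=40)  # inside the 24-bp stem
        report = build_report("gluk2_like", segment(structure), site, 83.0)
        assert len(report.candidates) == 2
        assert sorted(c.side for c in report.candidates) == ["3p", "5p"]
        assert sorted(c.bp_count for c in report.candidates) == [22, 25]
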