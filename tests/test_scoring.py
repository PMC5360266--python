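"""Residue pair scores, sequence scores and per-locus selection."""

import logging

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from isopick.fixtures import sp_score_oracle
from isopick.scoring import (
    ResidueColumnMap,
    ScoreTable,
    distance_scores,
    pair_agreement,
    residue_score,
    select_per_locus,
    sp_scores,
)
from isopick.seqio import Alignment
from tests.conftest import perturbations, random_alignment


# two hand-built 2-sequence maps: in the perturbed alignment the second
# residue of 'b' slid one column to the left
REF = Alignment(["a", "b"], ["MKV", "M-K"])
PERT_SAME = Alignment(["a", "b"], ["MKV", "M-K"])
PERT_SHIFT = Alignment(["a", "b"], ["MKV-", "M--K"])


def test_column_map_bijection_and_counts():
    cmap = ResidueColumnMap(REF)
    assert cmap.column_of("a", 1) == 0
    assert cmap.column_of("b", 2) == 2
    assert cmap.partner_of("a", 3, "b") == 2
    assert cmap.partner_of("b", 2, "a") == 3
    assert cmap.residues_in_column(0) == 2
    assert cmap.gaps_in_column(1) == 1
    with pytest.raises(IndexError):
        cmap.column_of("a", 4)


def test_partner_relation_is_symmetric_on_random_alignments():
    rng = np.random.default_rng(21)
    for _ in range(5):
        aln = random_alignment(4, 15, rng)
        cmap = ResidueColumnMap(aln)
        for i in aln.ids:
            for k in range(1, cmap.n_residues(i) + 1):
                for j in aln.ids:
                    if j == i:
                        continue
                    s = cmap.partner_of(i, k, j)
                    if s is not None:
                        assert cmap.partner_of(j, s, i) == k


def test_pair_agreement_identity_and_shift():
    ref_map = ResidueColumnMap(REF)
    assert pair_agreement(ref_map, ResidueColumnMap(PERT_SAME), "a", 3, "b") == 1
    # residue 2 of b no longer faces residue 3 of a after the shift
    assert pair_agreement(ref_map, ResidueColumnMap(PERT_SHIFT), "a", 3, "b") == 0


def test_pair_agreement_zero_when_partner_gapped_in_perturbation():
    ref = Alignment(["a", "b"], ["MK", "MK"])
    pert = Alignment(["a", "b"], ["MK-", "M-K"])
    assert pair_agreement(ResidueColumnMap(ref), ResidueColumnMap(pert),
                          "a", 2, "b") == 0


def test_pair_agreement_requires_reference_partner():
    ref_map = ResidueColumnMap(REF)
    with pytest.raises(ValueError):
        pair_agreement(ref_map, ref_map, "a", 2, "b")  # b gapped in ref col


def test_residue_score_lone_residue_rules():
    # column 2 of the reference holds only a's residue (m_k = 1)
    ref = Alignment(["a", "b", "c", "d"],
                    ["MKV", "M-V", "M-V", "M-V"])
    cmap = ResidueColumnMap(ref)
    assert residue_score(cmap, cmap, "a", 2, gap_variant=False) == 1.0
    # gap variant: -1/m_g with m_g = 3 gaps in that column
    assert residue_score(cmap, cmap, "a", 2, gap_variant=True) == \
        pytest.approx(-1.0 / 3.0)


def test_residue_score_identity_is_one():
    aln = Alignment(["a", "b", "c"], ["MKV", "MKV", "MKV"])
    cmap = ResidueColumnMap(aln)
    for k in (1, 2, 3):
        assert residue_score(cmap, cmap, "a", k) == 1.0


def test_identity_reduction_default_and_short():
    rng = np.random.default_rng(3)
    aln = random_alignment(5, 24, rng)
    table = sp_scores(aln, [aln, aln], "default")
    assert all(s == 1.0 for s in table.scores.values())
    short = sp_scores(aln, [aln], "short")
    lengths = aln.ungapped_lengths()
    for seq_id, score in short.scores.items():
        assert score == pytest.approx(lengths[seq_id] / aln.length)


def test_sp_scores_match_brute_force_oracle():
    rng = np.random.default_rng(17)
    for _ in range(25):
        m = int(rng.integers(3, 7))
        ell = int(rng.integers(8, 31))
        n = int(rng.integers(1, 4))
        ref = random_alignment(m, ell, rng)
        perts = perturbations(ref, n, rng)
        for variant in ("default", "gap", "short"):
            ours = sp_scores(ref, perts, variant)
            oracle = sp_score_oracle(ref, perts, variant)
            for seq_id in ours.ids:
                assert ours.scores[seq_id] == pytest.approx(
                    oracle.scores[seq_id], abs=1e-12)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_default_scores_lie_in_unit_interval(seed):
    rng = np.random.default_rng(seed)
    ref = random_alignment(int(rng.integers(3, 6)), int(rng.integers(6, 25)),
                           rng)
    perts = perturbations(ref, 2, rng)
    table = sp_scores(ref, perts, "default")
    assert all(0.0 <= s <= 1.0 for s in table.scores.values())


def test_scores_follow_ids_under_row_permutation():
    rng = np.random.default_rng(23)
    ref = random_alignment(5, 20, rng)
    perts = perturbations(ref, 2, rng)
    base = sp_scores(ref, perts, "default")

    order = [3, 1, 4, 0, 2]
    ref_p = Alignment([ref.ids[i] for i in order],
                      [ref.rows[i] for i in order])
    perts_p = [Alignment([p.ids[i] for i in order],
                         [p.rows[i] for i in order]) for p in perts]
    permuted = sp_scores(ref_p, perts_p, "default")
    for seq_id in base.ids:
        assert permuted.scores[seq_id] == pytest.approx(base.scores[seq_id])


def test_gap_variant_never_exceeds_default_and_matches_when_gapless():
    rng = np.random.default_rng(29)
    for _ in range(5):
        ref = random_alignment(4, 18, rng, gap_p=0.25)
        perts = perturbations(ref, 2, rng)
        default = sp_scores(ref, perts, "default")
        gap = sp_scores(ref, perts, "gap")
        has_gap = any("-" in row for row in ref.rows)
        for seq_id in default.ids:
            if has_gap:
                assert gap.scores[seq_id] <= default.scores[seq_id] + 1e-12
            else:
                assert gap.scores[seq_id] == pytest.approx(
                    default.scores[seq_id])


def test_sp_scores_rejects_mismatched_replicates():
    rng = np.random.default_rng(31)
    ref = random_alignment(4, 12, rng)
    bad = Alignment(["x0", "x1", "x2", "x3"], list(ref.rows))
    with pytest.raises(ValueError):
        sp_scores(ref, [bad], "default")


# --- distance scores ---------------------------------------------------------

TOY = Alignment(
    ["g1_a", "g1_b", "g2_a", "g2_b", "solo"],
    ["MKVLDEAD",
     "MKVL----",
     "MKVLDEAE",
     "MKVLDE--",
     "MKVLDEAD"],
)
TOY_LOCI = {"g1_a": "g1", "g1_b": "g1", "g2_a": "g2", "g2_b": "g2",
            "solo": "solo"}


def test_distance_scores_backbone_means_match_hand_arithmetic():
    from isopick.distmodels import modified_p_distance

    table = distance_scores(TOY, TOY_LOCI, wot=False)
    # the backbone is {solo}; every score is the distance to solo
    for seq_id in TOY.ids:
        if seq_id == "solo":
            continue
        expected = modified_p_distance(TOY.row(seq_id), TOY.row("solo"))
        assert table.scores[seq_id] == pytest.approx(expected)
    assert table.variant == "ds"


def test_distance_scores_zero_for_sequence_identical_to_backbone():
    table = distance_scores(TOY, TOY_LOCI, wot=False)
    assert table.scores["g1_a"] == 0.0  # identical to solo


def test_distance_scores_wot_means_match_hand_arithmetic():
    from isopick.distmodels import modified_p_distance

    table = distance_scores(TOY, TOY_LOCI, wot=True)
    for i, seq_id in enumerate(TOY.ids):
        expected = np.mean([modified_p_distance(TOY.rows[i], TOY.rows[j])
                            for j in range(len(TOY.ids)) if j != i])
        assert table.scores[seq_id] == pytest.approx(expected)
    assert table.variant == "ds_wot"


def test_distance_scores_empty_backbone_requires_wot():
    loci = dict(TOY_LOCI, solo="g2")
    with pytest.raises(ValueError, match="WOT"):
        distance_scores(TOY, loci, wot=False)


def test_wot_equals_backbone_mode_when_all_singletons():
    loci = {seq_id: seq_id for seq_id in TOY.ids}
    a = distance_scores(TOY, loci, wot=False)
    b = distance_scores(TOY, loci, wot=True)
    for seq_id in TOY.ids:
        assert a.scores[seq_id] == pytest.approx(b.scores[seq_id])


# --- selection ---------------------------------------------------------------

def test_selection_argmax_for_sp_and_argmin_for_ds():
    loci = {"a1": "g", "a2": "g", "b": "b"}
    sp = ScoreTable("default", {"a1": 0.91, "a2": 0.88, "b": 0.5}, n=1)
    assert select_per_locus(sp, loci) == {"g": "a1", "b": "b"}
    ds = ScoreTable("ds", {"a1": 0.12, "a2": 0.30, "b": 0.5}, n=0)
    assert select_per_locus(ds, loci) == {"g": "a1", "b": "b"}


def test_selection_tie_goes_to_smallest_id_with_warning(caplog):
    loci = {"z9": "g", "a1": "g"}
    table = ScoreTable("default", {"z9": 0.7, "a1": 0.7}, n=1)
    with caplog.at_level(logging.WARNING, logger="isopick.scoring"):
        assert select_per_locus(table, loci) == {"g": "a1"}
    assert any("tie" in rec.message for rec in caplog.records)


def test_selection_compares_full_precision_not_rounded():
    loci = {"a": "g", "b": "g"}
    table = ScoreTable("default", {"a": 0.9000004, "b": 0.9000003}, n=1)
    assert select_per_locus(table, loci) == {"g": "a"}
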