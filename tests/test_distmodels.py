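"""Distance estimators: observed proportions, closed forms, ML distances."""

import subprocess

import numpy as np
import pytest

from isopick.distmodels import (
    DEFAULT_CEILING,
    DistanceMatrix,
    ModelSpec,
    correct_distance,
    distance_matrix,
    gamma_category_rates,
    is_saturated,
    ml_matrix_distance,
    modified_p_distance,
    p_distance,
    rate_matrix,
    transition_matrix,
)
from isopick.distmodels import AA_ORDER
from isopick.seqio import Alignment
from tests.conftest import AA


@pytest.mark.parametrize("pair, expected", [
    (("MKV", "MKV"), 0.0),
    (("MKVL", "MK-L"), 0.0),      # 3 comparable positions, 0 differ
    (("MKVL", "AKVI"), 0.5),      # 2 of 4 differ
])
def test_p_distance_hand_counts(pair, expected):
    assert p_distance(*pair) == pytest.approx(expected)


@pytest.mark.parametrize("pair, expected", [
    (("MKVL", "MK-L"), 0.25),         # gap counts as 21st state
    (("MKVLDEAD", "MKVL----"), 0.5),  # exon-skipping pair stays far from 1
    (("MK-L", "MK-L"), 0.0),
])
def test_modified_p_distance_hand_counts(pair, expected):
    assert modified_p_distance(*pair) == pytest.approx(expected)


def test_modified_p_distance_keeps_exon_skips_unsaturated():
    # the standard p-distance sees only identical positions here (0.0) while
    # the gap-as-state distance reflects the missing exon proportionally
    row_a, row_b = "MKVLDEAD", "MKVL----"
    assert p_distance(row_a, row_b) == 0.0
    assert modified_p_distance(row_a, row_b) == 0.5 < 0.99


def test_length_mismatch_rejected():
    with pytest.raises(ValueError):
        p_distance("MKV", "MK")
    with pytest.raises(ValueError):
        modified_p_distance("MKV", "MK")


def test_no_comparable_positions_warns_and_returns_zero():
    with pytest.warns(UserWarning):
        assert p_distance("M--", "-KV") == 0.0


def test_x_positions_are_excluded_everywhere():
    assert p_distance("MXVL", "MAVL") == 0.0
    assert modified_p_distance("MXVL", "MAVL") == 0.0


@pytest.mark.parametrize("model", [
    ModelSpec("poisson"), ModelSpec("poisson", gamma_alpha=0.5),
    ModelSpec("pam_kimura"), ModelSpec("jtt_approx"),
])
def test_zero_proportion_gives_zero_distance(model):
    assert correct_distance(0.0, model) == 0.0


def test_closed_forms_match_high_precision_evaluation():
    assert correct_distance(0.5, ModelSpec("poisson")) == pytest.approx(
        0.693147, abs=5e-7)
    # Kimura's PAM approximation: -ln(1 - p - 0.2 p^2) at p = 0.5
    assert correct_distance(0.5, ModelSpec("pam_kimura")) == pytest.approx(
        0.798508, abs=5e-7)
    alpha = 0.7
    expected = alpha * ((1 - 0.3) ** (-1 / alpha) - 1)
    assert correct_distance(0.3, ModelSpec("poisson", gamma_alpha=alpha)) == \
        pytest.approx(expected)


def test_gamma_poisson_approaches_poisson_for_large_alpha():
    for p in (0.1, 0.4, 0.7):
        plain = correct_distance(p, ModelSpec("poisson"))
        mixed = correct_distance(p, ModelSpec("poisson", gamma_alpha=1e6))
        assert abs(plain - mixed) < 1e-4


@pytest.mark.parametrize("model", [
    ModelSpec("poisson"), ModelSpec("poisson", gamma_alpha=1.0),
    ModelSpec("pam_kimura"), ModelSpec("jtt_approx"),
])
def test_correction_is_monotone_in_p(model):
    grid = np.linspace(0.0, 0.80, 60)
    values = [correct_distance(p, model) for p in grid]
    assert all(b > a for a, b in zip(values, values[1:]))


def test_saturation_caps_at_ceiling():
    assert correct_distance(1.0, ModelSpec("poisson")) == DEFAULT_CEILING
    assert is_saturated(correct_distance(0.9, ModelSpec("pam_kimura")))
    assert correct_distance(0.99, ModelSpec("poisson"), ceiling=3.0) == 3.0


def test_invalid_model_and_gamma_rejected():
    with pytest.raises(ValueError):
        ModelSpec("hky85")
    with pytest.raises(ValueError):
        ModelSpec("poisson", gamma_alpha=-1.0)


def test_rate_matrices_are_proper_and_normalised():
    for name in ("pam", "jtt", "wag", "lg", "blosum62"):
        rates, pi = rate_matrix(name)
        assert pi.shape == (20,)
        assert pi.sum() == pytest.approx(1.0)
        assert np.all(pi > 0)
        # rows sum to zero; detailed balance; unit expected rate
        assert np.allclose(rates.sum(axis=1), 0.0, atol=1e-10)
        assert np.allclose(pi[:, None] * rates, (pi[:, None] * rates).T,
                           atol=1e-10)
        assert -(pi * np.diag(rates)).sum() == pytest.approx(1.0)


def test_transition_matrix_rows_are_distributions():
    for t in (0.01, 0.5, 5.0):
        p = transition_matrix("lg", t)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-8)
        assert np.all(p > 0)
    mixed = transition_matrix("lg", 0.5, gamma_alpha=0.8)
    assert np.allclose(mixed.sum(axis=1), 1.0, atol=1e-8)


def test_gamma_category_rates_have_unit_mean():
    for alpha in (0.3, 1.0, 5.0):
        rates = gamma_category_rates(alpha)
        assert rates.mean() == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(rates) > 0)


def _simulate_pair(name: str, t: float, length: int,
                   rng: np.random.Generator) -> tuple[str, str]:
    _, pi = rate_matrix(name)
    p = transition_matrix(name, t)
    x = rng.choice(20, size=length, p=pi)
    u = rng.random(length)
    y = (p[x].cumsum(axis=1) < u[:, None]).sum(axis=1)
    # codes follow the model's own residue order
    return ("".join(AA_ORDER[c] for c in x), "".join(AA_ORDER[c] for c in y))


def test_ml_distance_is_zero_for_identical_sequences():
    rng = np.random.default_rng(0)
    seq = "".join(AA[c] for c in rng.integers(0, 20, 300))
    assert ml_matrix_distance(seq, seq, "lg") < 1e-4


def test_ml_distance_recovers_simulated_truth():
    # parameter-recovery oracle: simulate under the same eigendecomposition
    rng = np.random.default_rng(42)
    estimates = []
    for _ in range(20):
        row_a, row_b = _simulate_pair("lg", 0.5, 10_000, rng)
        estimates.append(ml_matrix_distance(row_a, row_b, "lg"))
    mean = float(np.mean(estimates))
    assert abs(mean - 0.5) < 0.05
    assert abs(mean - 0.5) / 0.5 < 0.05  # bias below 5%


def test_ml_distance_saturates_on_unalignable_sequences():
    # five positions, all different
    d = ml_matrix_distance("ARNDC", "LKIVW", "lg")
    assert is_saturated(d)
    assert d == DEFAULT_CEILING


def test_ml_distance_matches_independent_reference_implementation(tmp_path):
    # cross-check against the ML distance of the phangorn R package
    rng = np.random.default_rng(7)
    row_a, row_b = _simulate_pair("lg", 0.4, 2_000, rng)
    fasta = tmp_path / "pair.fasta"
    fasta.write_text(f">a\n{row_a}\n>b\n{row_b}\n")
    script = tmp_path / "dist.R"
    script.write_text(
        'suppressMessages(library(phangorn));'
        f'aln <- read.phyDat("{fasta}", format="fasta", type="AA");'
        'cat(as.matrix(dist.ml(aln, model="LG"))[1,2])'
    )
    res = subprocess.run(["Rscript", str(script)], capture_output=True,
                         text=True, timeout=300)
    if res.returncode != 0:
        pytest.xfail(f"reference implementation unavailable: {res.stderr[:200]}")
    reference = float(res.stdout.strip())
    ours = ml_matrix_distance(row_a, row_b, "lg")
    assert ours == pytest.approx(reference, rel=0.02)


def test_distance_matrix_of_identical_sequences_is_zero():
    aln = Alignment(["a", "b", "c"], ["MKVLDE"] * 3)
    dm = distance_matrix(aln, ModelSpec("poisson"))
    assert np.allclose(dm.values, 0.0)
    assert not dm.saturated.any()


def test_distance_matrix_symmetry_on_random_alignments():
    from tests.conftest import random_alignment

    rng = np.random.default_rng(9)
    for model in (ModelSpec("pdist"), ModelSpec("modified_pdist"),
                  ModelSpec("jtt_approx")):
        aln = random_alignment(5, 40, rng)
        dm = distance_matrix(aln, model)
        assert np.allclose(dm.values, dm.values.T)
        assert np.allclose(np.diag(dm.values), 0.0)


def test_p_distance_matrix_matches_hand_counts():
    aln = Alignment(["a", "b", "c"], ["MKVL", "MKLL", "AK-L"])
    dm = distance_matrix(aln, ModelSpec("pdist"))
    assert dm[("a", "b")] == pytest.approx(0.25)
    assert dm[("a", "c")] == pytest.approx(1 / 3)
    assert dm[("b", "c")] == pytest.approx(1 / 3)


def test_phylip_export_layout():
    dm = DistanceMatrix(["alpha", "beta", "gamma"],
                        np.array([[0, .1, .2], [.1, 0, .3], [.2, .3, 0]]))
    text = dm.to_phylip()
    lines = text.splitlines()
    assert lines[0] == "3"
    assert lines[1].startswith("alpha")
    assert "0.100000" in lines[1]
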