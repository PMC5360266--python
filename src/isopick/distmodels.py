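"""Pairwise evolutionary distances between aligned protein sequences.

Three families of estimators are provided:

* observed proportions: the p-distance and the modified p-distance in
  which a gap counts as a 21st character state (so isoforms differing by
  an exon-skipping event are not pushed towards saturation);
* closed-form corrections of the p-distance: Poisson -ln(1-p), its Gamma
  generalisation alpha*((1-p)^(-1/alpha)-1), the Kimura approximation of
  PAM distances -ln(1 - p - 0.2 p^2), and a Gamma-Poisson approximation
  of JTT distances;
* maximum-likelihood distances under the empirical replacement matrices
  Dayhoff/PAM, JTT, WAG and LG (or a rate matrix derived from BLOSUM62
  by log-odds inversion), optionally with discrete-Gamma rate mixing.

Positions holding an X (unknown residue) are excluded from every
comparison.  Distances at or beyond the saturation ceiling (default 10
substitutions/site) are capped there and flagged saturated.
"""

from __future__ import annotations

import functools
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

from ._empirical_data import (
    AA_ORDER,
    DAYHOFF_EXCH,
    DAYHOFF_FREQ,
    JTT_EXCH,
    JTT_FREQ,
    LG_EXCH,
    LG_FREQ,
    WAG_EXCH,
    WAG_FREQ,
)

DEFAULT_CEILING = 10.0
#: shape constant of the Gamma-Poisson approximation to JTT distances
JTT_APPROX_ALPHA = 2.4

GAP_CODE = 20
X_CODE = 21
_AA_INDEX = {aa: i for i, aa in enumerate(AA_ORDER)}

CLOSED_FORM_MODELS = frozenset({"poisson", "pam_kimura", "jtt_approx"})
ML_MODELS = frozenset({"pam_ml", "jtt_ml", "wag_ml", "lg_ml", "blosum62_ml"})
PROPORTION_MODELS = frozenset({"pdist", "modified_pdist"})
ALL_MODELS = CLOSED_FORM_MODELS | ML_MODELS | PROPORTION_MODELS


@dataclass(frozen=True)
class ModelSpec:
    """Choice of substitution model plus optional Gamma shape parameter."""

    model: str = "jtt_approx"
    gamma_alpha: float | None = None

    def __post_init__(self) -> None:
        if self.model not in ALL_MODELS:
            raise ValueError(
                f"unknown model {self.model!r}; choose from {sorted(ALL_MODELS)}"
            )
        if self.gamma_alpha is not None and self.gamma_alpha <= 0:
            raise ValueError("gamma_alpha must be positive")


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with zero diagonal."""

    ids: list[str]
    values: np.ndarray
    saturated: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape does not match ids")
        if self.saturated is None:
            self.saturated = np.zeros_like(self.values, dtype=bool)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i, j = (self.ids.index(p) for p in pair)
        return float(self.values[i, j])

    def to_phylip(self) -> str:
        """PHYLIP square distance-matrix format."""
        lines = [f"{len(self.ids)}"]
        for seq_id, row in zip(self.ids, self.values):
            name = seq_id[:10].ljust(10)
            lines.append(name + "  " + "  ".join(f"{x:.6f}" for x in row))
        return "\n".join(lines) + "\n"


def encode_row(row: str) -> np.ndarray:
    """Encode an aligned row as int codes: 0-19 residues, 20 gap, 21 X."""
    return np.fromiter(
        (_AA_INDEX.get(ch, GAP_CODE if ch == "-" else X_CODE) for ch in row),
        dtype=np.int8,
        count=len(row),
    )


def _check_pair(row_a: str, row_b: str) -> tuple[np.ndarray, np.ndarray]:
    if len(row_a) != len(row_b):
        raise ValueError("aligned rows must have equal length")
    return encode_row(row_a), encode_row(row_b)


def p_distance(row_a: str, row_b: str) -> float:
    """Proportion of differing sites among sites where both rows have residues."""
    a, b = _check_pair(row_a, row_b)
    comparable = (a < GAP_CODE) & (b < GAP_CODE)
    n = int(comparable.sum())
    if n == 0:
        warnings.warn("no comparable residue pairs; p-distance set to 0",
                      stacklevel=2)
        return 0.0
    return float((a[comparable] != b[comparable]).sum()) / n


def modified_p_distance(row_a: str, row_b: str) -> float:
    """p-distance with the gap as an extra character state.

    A residue facing a gap counts as a difference; columns gapped in both
    rows (or holding an X in either) are excluded.  The denominator is the
    number of columns where at least one row carries a residue.
    """
    a, b = _check_pair(row_a, row_b)
    counted = ~((a == GAP_CODE) & (b == GAP_CODE)) & (a != X_CODE) & (b != X_CODE)
    n = int(counted.sum())
    if n == 0:
        raise ValueError("no countable columns between the two rows")
    return float((a[counted] != b[counted]).sum()) / n


def correct_distance(p: float, model: ModelSpec,
                     ceiling: float = DEFAULT_CEILING) -> float:
    """Closed-form evolutionary distance from an observed proportion p.

    Saturated inputs (arguments at or beyond the formula's domain limit)
    return the ceiling.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"proportion p={p} outside [0, 1]")
    if model.model in PROPORTION_MODELS:
        return p
    if model.model == "poisson":
        if model.gamma_alpha is None:
            arg = 1.0 - p
            d = -np.log(arg) if arg > 0 else np.inf
        else:
            d = _gamma_poisson(p, model.gamma_alpha)
    elif model.model == "pam_kimura":
        arg = 1.0 - p - 0.2 * p * p
        d = -np.log(arg) if arg > 0 else np.inf
    elif model.model == "jtt_approx":
        alpha = model.gamma_alpha if model.gamma_alpha is not None else JTT_APPROX_ALPHA
        d = _gamma_poisson(p, alpha)
    else:
        raise ValueError(f"{model.model!r} has no closed form; use ml_matrix_distance")
    return float(min(d, ceiling))


def _gamma_poisson(p: float, alpha: float) -> float:
    if p >= 1.0:
        return np.inf
    return alpha * ((1.0 - p) ** (-1.0 / alpha) - 1.0)


# --- empirical rate matrices -------------------------------------------------

_EMPIRICAL = {
    "pam": (DAYHOFF_EXCH, DAYHOFF_FREQ),
    "jtt": (JTT_EXCH, JTT_FREQ),
    "wag": (WAG_EXCH, WAG_FREQ),
    "lg": (LG_EXCH, LG_FREQ),
}


def _exchangeability_matrix(triangle: list[float]) -> np.ndarray:
    # column-major lower triangle: (2,1), (3,1), ..., (20,1), (3,2), ...
    s = np.zeros((20, 20))
    pos = 0
    for j in range(19):
        for i in range(j + 1, 20):
            s[i, j] = s[j, i] = triangle[pos]
            pos += 1
    return s


@functools.lru_cache(maxsize=None)
def _blosum62_joint() -> tuple[np.ndarray, np.ndarray]:
    """Invert the BLOSUM62 log-odds scores to joint probabilities.

    BLOSUM62 entries are half-bit rounded log-odds s = 2*log2(q/(p_x p_y)),
    so the odds ratios are O = 2^(s/2) and a self-consistent background
    satisfies sum_y p_y O_xy = 1 for every x (the marginals of
    q = p_x p_y O_xy must reproduce p).  That is a linear system in p;
    score rounding makes it only approximately satisfiable, so the
    solution is renormalised.
    """
    from Bio.Align import substitution_matrices

    blosum = substitution_matrices.load("BLOSUM62")
    s = np.array([[blosum[x, y] for y in AA_ORDER] for x in AA_ORDER])
    odds = np.exp2(s / 2.0)
    p = np.linalg.solve(odds, np.ones(20))
    if (p <= 0).any():
        raise RuntimeError("BLOSUM62 inversion produced negative frequencies")
    p = p / p.sum()
    q = np.outer(p, p) * odds
    q /= q.sum()
    return q, p


@functools.lru_cache(maxsize=None)
def rate_matrix(name: str) -> tuple[np.ndarray, np.ndarray]:
    """Normalised rate matrix and equilibrium frequencies for a model name.

    The matrix is scaled so the expected rate at equilibrium is one
    substitution per site per unit time.
    """
    if name in _EMPIRICAL:
        triangle, freqs = _EMPIRICAL[name]
        s = _exchangeability_matrix(list(triangle))
        pi = np.asarray(freqs, dtype=float)
    elif name == "blosum62":
        q, pi = _blosum62_joint()
        s = q / np.outer(pi, pi)
        np.fill_diagonal(s, 0.0)
    else:
        raise ValueError(f"unknown rate model {name!r}")
    pi = pi / pi.sum()
    rates = s * pi[None, :]
    np.fill_diagonal(rates, 0.0)
    np.fill_diagonal(rates, -rates.sum(axis=1))
    mu = -(pi * np.diag(rates)).sum()
    return rates / mu, pi


@functools.lru_cache(maxsize=None)
def _eigen(name: str):
    rates, pi = rate_matrix(name)
    sqrt_pi = np.sqrt(pi)
    sym = rates * (sqrt_pi[:, None] / sqrt_pi[None, :])
    w, vec = np.linalg.eigh(0.5 * (sym + sym.T))
    left = vec.T * sqrt_pi[None, :]          # rows of V^T D^(1/2)
    right = vec / sqrt_pi[:, None]           # D^(-1/2) V
    return pi, w, right, left


def gamma_category_rates(alpha: float, ncat: int = 4) -> np.ndarray:
    """Mean rates of ``ncat`` equal-probability discrete Gamma categories."""
    edges = gamma_dist.ppf(np.arange(1, ncat) / ncat, a=alpha, scale=1.0 / alpha)
    upper = np.concatenate([edges, [np.inf]])
    lower = np.concatenate([[0.0], edges])
    mass = gammainc(alpha + 1.0, alpha * upper) - gammainc(alpha + 1.0, alpha * lower)
    return ncat * mass


def transition_matrix(name: str, t: float, gamma_alpha: float | None = None,
                      ncat: int = 4) -> np.ndarray:
    """P(t) for the named model, optionally Gamma rate-mixed (4 categories)."""
    pi, w, right, left = _eigen(name)
    if gamma_alpha is None:
        p = (right * np.exp(w * t)[None, :]) @ left
    else:
        p = np.zeros((20, 20))
        for rate in gamma_category_rates(gamma_alpha, ncat):
            p += (right * np.exp(w * rate * t)[None, :]) @ left
        p /= ncat
    return np.clip(p, 1e-300, None)


def _pair_counts(row_a: str, row_b: str) -> np.ndarray:
    a, b = _check_pair(row_a, row_b)
    comparable = (a < GAP_CODE) & (b < GAP_CODE)
    counts = np.zeros((20, 20))
    np.add.at(counts, (a[comparable], b[comparable]), 1.0)
    return counts


def ml_matrix_distance(row_a: str, row_b: str, rate_model: str = "lg",
                       gamma_alpha: float | None = None,
                       ceiling: float = DEFAULT_CEILING) -> float:
    """Maximum-likelihood pairwise distance under an empirical rate matrix.

    Maximises sum over comparable columns of log(pi_x * P_xy(t)) for
    t in [1e-6, ceiling].  An optimum within 1e-3 of the ceiling is
    snapped to the ceiling (saturated).
    """
    counts = _pair_counts(row_a, row_b)
    if counts.sum() == 0:
        raise ValueError("no comparable residue columns for ML distance")
    pi, _, _, _ = _eigen(rate_model)
    log_pi = np.log(pi)

    def neg_ll(t: float) -> float:
        p = transition_matrix(rate_model, t, gamma_alpha)
        return -float((counts * (log_pi[:, None] + np.log(p))).sum())

    res = minimize_scalar(neg_ll, bounds=(1e-6, ceiling), method="bounded",
                          options={"xatol": 1e-6})
    t_hat = float(res.x)
    if ceiling - t_hat < 1e-3:
        return ceiling
    return t_hat


def is_saturated(value: float, ceiling: float = DEFAULT_CEILING) -> bool:
    return value >= ceiling


def distance_matrix(aln, model: ModelSpec,
                    ceiling: float = DEFAULT_CEILING) -> DistanceMatrix:
    """All-pairs distance matrix of an Alignment under a ModelSpec."""
    ids = list(aln.ids)
    m = len(ids)
    values = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            row_i, row_j = aln.rows[i], aln.rows[j]
            if model.model == "pdist":
                d = p_distance(row_i, row_j)
            elif model.model == "modified_pdist":
                d = modified_p_distance(row_i, row_j)
            elif model.model in CLOSED_FORM_MODELS:
                d = correct_distance(p_distance(row_i, row_j), model, ceiling)
            else:
                d = ml_matrix_distance(row_i, row_j,
                                       model.model.removesuffix("_ml"),
                                       model.gamma_alpha, ceiling)
            values[i, j] = values[j, i] = d
    return DistanceMatrix(ids, values, saturated=values >= ceiling)
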