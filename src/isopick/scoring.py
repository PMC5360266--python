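"""Per-sequence alignment-confidence scores and per-locus isoform selection.

The sum-of-pairs (SP) score of sequence i asks, for every residue k of i
and every other sequence j with a residue in the same reference-alignment
column, whether the same two residues still face each other in a perturbed
realignment.  Residue pairings are tracked by residue ordinal (the k-th
residue of a sequence), never by column index, so reference and perturbed
alignments of different lengths are directly comparable.

Variants:

* default — R_ik(b) is the mean agreement over the m_k - 1 partners;
  S_i is the mean of R_ik over the sequence's own residues (0 <= S_i <= 1).
* gap — each agreement is divided by the number of gaps m_g in the
  reference column, penalising sequences that force gaps on others; a
  residue aligned against nothing scores -1/m_g instead of 1.
* short — S_i divides the summed residue scores by the reference
  alignment length instead of the sequence length, penalising short
  isoforms that are otherwise well aligned.
* ds / ds_wot — no bootstrap at all: S_i is the mean modified p-distance
  to the isoform-free backbone sequences (ds) or to all other sequences
  (ds_wot); selection then minimises instead of maximising.

Residue ordinals k are 1-based throughout the public surface.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .distmodels import GAP_CODE, encode_row, modified_p_distance
from .seqio import Alignment

logger = logging.getLogger(__name__)

SP_VARIANTS = ("default", "gap", "short")
DS_VARIANTS = ("ds", "ds_wot")


class ResidueColumnMap:
    """Bijection between (sequence, residue ordinal) and alignment columns."""

    def __init__(self, aln: Alignment):
        self.ids = list(aln.ids)
        self._index = {seq_id: i for i, seq_id in enumerate(self.ids)}
        codes = np.stack([encode_row(row) for row in aln.rows])
        residue = codes != GAP_CODE
        # columns_of[i]: 0-based column of each residue ordinal of sequence i
        self.columns_of = [np.flatnonzero(residue[i])
                           for i in range(len(self.ids))]
        # ordinal_at[i, col]: 1-based residue ordinal of i at col, 0 if gap
        self.ordinal_at = np.where(residue, residue.cumsum(axis=1), 0)
        self.m_k_per_column = residue.sum(axis=0)
        self.m = len(self.ids)
        self.length = aln.length
        if (self.m_k_per_column < 1).any():
            raise ValueError("alignment contains an all-gap column")

    def n_residues(self, seq_id: str) -> int:
        return len(self.columns_of[self._index[seq_id]])

    def column_of(self, seq_id: str, k: int) -> int:
        """0-based column of the k-th (1-based) residue of a sequence."""
        cols = self.columns_of[self._index[seq_id]]
        if not 1 <= k <= len(cols):
            raise IndexError(f"residue ordinal {k} out of range for {seq_id!r}")
        return int(cols[k - 1])

    def partner_of(self, seq_id: str, k: int, other_id: str) -> int | None:
        """Residue ordinal of ``other_id`` in the column of (seq_id, k)."""
        col = self.column_of(seq_id, k)
        ordinal = int(self.ordinal_at[self._index[other_id], col])
        return ordinal if ordinal > 0 else None

    def residues_in_column(self, col: int) -> int:
        return int(self.m_k_per_column[col])

    def gaps_in_column(self, col: int) -> int:
        return self.m - int(self.m_k_per_column[col])


@dataclass
class ScoreTable:
    """Per-sequence scores S_i plus the variant that produced them."""

    variant: str
    scores: dict[str, float]
    n: int = 0
    residue_scores: dict[str, np.ndarray] | None = field(default=None, repr=False)

    @property
    def ids(self) -> list[str]:
        return list(self.scores)


def pair_agreement(ref_map: ResidueColumnMap, pert_map: ResidueColumnMap,
                   seq_id: str, k: int, other_id: str) -> int:
    """p_ijk: 1 iff residue k of i faces the same residue of j in both maps.

    Defined only when j has a residue in the reference column of (i, k).
    """
    if other_id == seq_id:
        raise ValueError("pair agreement needs two distinct sequences")
    ref_partner = ref_map.partner_of(seq_id, k, other_id)
    if ref_partner is None:
        raise ValueError(
            f"{other_id!r} has a gap in the reference column of "
            f"({seq_id!r}, {k}); p_ijk is undefined"
        )
    return int(pert_map.partner_of(seq_id, k, other_id) == ref_partner)


def _partner_matrix(cmap: ResidueColumnMap, i: int) -> np.ndarray:
    """(m, l_i) matrix of partner ordinals for sequence index i (0 = gap)."""
    cols = cmap.columns_of[i]
    return cmap.ordinal_at[:, cols]


def _replicate_residue_scores(ref_map: ResidueColumnMap,
                              pert_map: ResidueColumnMap,
                              gap_variant: bool) -> list[np.ndarray]:
    """R_ik(b) for every sequence i and residue k, for one replicate b."""
    out: list[np.ndarray] = []
    m = ref_map.m
    for i in range(m):
        cols = ref_map.columns_of[i]
        ref_partners = _partner_matrix(ref_map, i)
        pert_partners = _partner_matrix(pert_map, i)
        in_ref = ref_partners > 0
        in_ref[i, :] = False  # exclude i itself from its own partner set
        agree = in_ref & (ref_partners == pert_partners)
        m_k = ref_map.m_k_per_column[cols].astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = agree.sum(axis=0) / (m_k - 1.0)
        if gap_variant:
            m_g = (m - m_k)
            m_g[m_g == 0] = 1.0
            r = r / m_g
            r[m_k == 1] = -1.0 / m_g[m_k == 1]
        else:
            r[m_k == 1] = 1.0
        out.append(r)
    return out


def residue_score(ref_map: ResidueColumnMap, pert_map: ResidueColumnMap,
                  seq_id: str, k: int, gap_variant: bool = False) -> float:
    """R_ik(b) for a single residue of a single sequence."""
    i = ref_map.ids.index(seq_id)
    scores = _replicate_residue_scores(ref_map, pert_map, gap_variant)[i]
    if not 1 <= k <= len(scores):
        raise IndexError(f"residue ordinal {k} out of range for {seq_id!r}")
    return float(scores[k - 1])


def sp_scores(ref: Alignment, perturbed: Sequence[Alignment],
              variant: str = "default",
              keep_residue_scores: bool = False) -> ScoreTable:
    """Sum-of-pairs scores of every sequence over a set of perturbed alignments."""
    if variant not in SP_VARIANTS:
        raise ValueError(f"unknown SP variant {variant!r}")
    if not perturbed:
        raise ValueError("need at least one perturbed alignment")
    ref_map = ResidueColumnMap(ref)
    for pert in perturbed:
        if list(pert.ids) != list(ref.ids):
            raise ValueError("perturbed alignment ids differ from the reference")

    n = len(perturbed)
    totals = [np.zeros(len(ref_map.columns_of[i])) for i in range(ref_map.m)]
    gap_variant = variant == "gap"
    for pert in perturbed:
        pert_map = ResidueColumnMap(pert)
        for i, r in enumerate(_replicate_residue_scores(ref_map, pert_map,
                                                        gap_variant)):
            totals[i] += r
    means = [total / n for total in totals]

    scores: dict[str, float] = {}
    for i, seq_id in enumerate(ref.ids):
        if variant == "short":
            scores[seq_id] = float(means[i].sum() / ref.length)
        else:
            scores[seq_id] = float(means[i].mean())
    residue_scores = ({seq_id: means[i] for i, seq_id in enumerate(ref.ids)}
                      if keep_residue_scores else None)
    return ScoreTable(variant=variant, scores=scores, n=n,
                      residue_scores=residue_scores)


def distance_scores(ref: Alignment, locus_map: Mapping[str, str],
                    wot: bool = False) -> ScoreTable:
    """Distance scores: mean modified p-distance to the comparison set.

    Without ``wot`` the comparison set is the backbone of isoform-free
    (singleton-locus) sequences; with ``wot`` it is every other sequence.
    """
    ids = list(ref.ids)
    gene_sizes: dict[str, int] = {}
    for seq_id in ids:
        gene = locus_map.get(seq_id, seq_id)
        gene_sizes[gene] = gene_sizes.get(gene, 0) + 1
    backbone = {seq_id for seq_id in ids
                if gene_sizes[locus_map.get(seq_id, seq_id)] == 1}
    if not wot and not backbone:
        raise ValueError(
            "every gene has multiple isoforms, so the isoform-free backbone "
            "is empty; rerun with the with-other-transcripts (WOT) option"
        )

    m = len(ids)
    d = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            d[i, j] = d[j, i] = modified_p_distance(ref.rows[i], ref.rows[j])

    scores: dict[str, float] = {}
    for i, seq_id in enumerate(ids):
        if wot:
            others = [j for j in range(m) if j != i]
        else:
            others = [j for j in range(m) if ids[j] in backbone and j != i]
        if not others:
            logger.warning("no comparison sequences for %s; score set to 0",
                           seq_id)
            scores[seq_id] = 0.0
        else:
            scores[seq_id] = float(d[i, others].mean())
    return ScoreTable(variant="ds_wot" if wot else "ds", scores=scores, n=0)


def select_per_locus(scores: ScoreTable,
                     locus_map: Mapping[str, str]) -> dict[str, str]:
    """One winning sequence per gene: best score (SP) or smallest (DS).

    Exact ties go to the lexicographically smallest identifier, with a
    warning.  Selection compares full precision, not the printed rounding.
    """
    minimise = scores.variant in DS_VARIANTS
    by_gene: dict[str, list[str]] = {}
    for seq_id in scores.ids:
        by_gene.setdefault(locus_map.get(seq_id, seq_id), []).append(seq_id)

    selection: dict[str, str] = {}
    for gene, members in by_gene.items():
        key = (min if minimise else max)(scores.scores[s] for s in members)
        winners = sorted(s for s in members if scores.scores[s] == key)
        if len(winners) > 1:
            logger.warning("tie on gene %s between %s; keeping %s",
                           gene, winners, winners[0])
        selection[gene] = winners[0]
    return selection
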