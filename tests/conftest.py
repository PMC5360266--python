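"""Shared fixtures and helpers for the test suite.

Everything is generated programmatically; no data files are read.
"""

from __future__ import annotations

import numpy as np
import pytest

from isopick.seqio import Alignment, SequenceRecord, SequenceSet

AA = "ACDEFGHIKLMNPQRSTVWY"


def random_alignment(m: int, ell: int, rng: np.random.Generator,
                     gap_p: float = 0.2) -> Alignment:
    """Random alignment with no all-gap column and no all-gap row."""
    while True:
        rows = ["".join("-" if rng.random() < gap_p else AA[rng.integers(20)]
                        for _ in range(ell))
                for _ in range(m)]
        if all(any(row[c] != "-" for row in rows) for c in range(ell)) and \
                all(row.count("-") < ell for row in rows):
            return Alignment([f"s{i}" for i in range(m)], rows)


def shuffle_realign(aln: Alignment,
                    rng: np.random.Generator) -> Alignment | None:
    """Same residues, gap positions re-drawn: a synthetic 'realignment'."""
    rows = []
    for row in aln.rows:
        residues = row.replace("-", "")
        gap_cols = set(map(int, rng.choice(len(row),
                                           size=len(row) - len(residues),
                                           replace=False)))
        it = iter(residues)
        rows.append("".join("-" if c in gap_cols else next(it)
                            for c in range(len(row))))
    if all(any(row[c] != "-" for row in rows) for c in range(len(rows[0]))):
        return Alignment(list(aln.ids), rows)
    return None


def perturbations(aln: Alignment, n: int,
                  rng: np.random.Generator) -> list[Alignment]:
    out: list[Alignment] = []
    while len(out) < n:
        pert = shuffle_realign(aln, rng)
        if pert is not None:
            out.append(pert)
    return out


@pytest.fixture
def toy_seqs() -> SequenceSet:
    return SequenceSet([
        SequenceRecord("g1_a", "MKVLDEADRLKM", locus="g1"),
        SequenceRecord("g1_b", "MKVLRLKM", locus="g1"),
        SequenceRecord("g2_a", "MKVLDEADKLKM", locus="g2"),
        SequenceRecord("g2_b", "MKVLDEADKLK", locus="g2"),
        SequenceRecord("solo", "MKVLDEADRLKL"),
    ])


@pytest.fixture
def identity_alignment() -> Alignment:
    rows = ["MKVLDEAD", "MKVLDEAD", "MKVLDEAD"]
    return Alignment(["a", "b", "c"], rows)
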