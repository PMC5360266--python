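"""File input/output: FASTA, locus-tag tables, score files and filtered datasets.

Sequence identifiers are always the full FASTA header up to the first
whitespace (example headers contain ``|`` characters, so splitting on ``|``
would be unsafe).  The gap character is ``-``; ``.`` is converted to ``-``
and residues are upper-cased on read.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: legal residue alphabet: the 20 amino acids plus X (unknown)
RESIDUE_ALPHABET = frozenset(AMINO_ACIDS + "X")
GAP = "-"


class SequenceFormatError(ValueError):
    """Raised when an input file violates the sequence contracts."""


@dataclass
class SequenceRecord:
    """One named, unaligned protein sequence.

    Parameters
    ----------
    id : str
        Unique identifier (FASTA header up to the first whitespace).
    residues : str
        Residues over the 20 amino-acid letters plus ``X``; never contains
        gap characters.
    locus : str, optional
        Gene identifier.  Sequences sharing a locus are alternative
        isoforms of one gene.
    description : str, optional
        Full original FASTA header (used verbatim when writing output).
    """

    id: str
    residues: str
    locus: str | None = None
    description: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceFormatError("sequence identifier must be non-empty")
        if not self.residues:
            raise SequenceFormatError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - RESIDUE_ALPHABET
        if bad:
            raise SequenceFormatError(
                f"sequence {self.id!r} contains illegal characters {sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class SequenceSet:
    """Ordered collection of sequence records with unique identifiers."""

    records: list[SequenceRecord]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.id in seen:
                raise SequenceFormatError(f"duplicate identifier {rec.id!r}")
            seen.add(rec.id)

    @property
    def m(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> list[str]:
        return [rec.id for rec in self.records]

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, seq_id: str) -> SequenceRecord:
        for rec in self.records:
            if rec.id == seq_id:
                return rec
        raise KeyError(seq_id)

    def locus_map(self) -> dict[str, str]:
        """Map sequence id -> gene id; unlabelled records are singleton loci."""
        return {rec.id: (rec.locus if rec.locus is not None else rec.id)
                for rec in self.records}

    def apply_locus_tags(self, tags: Mapping[str, str]) -> None:
        """Attach gene labels from a locus-tag mapping (see read_locus_tags)."""
        known = set(self.ids)
        for seq_id in tags:
            if seq_id not in known:
                warnings.warn(
                    f"locus-tag file lists {seq_id!r} absent from the dataset",
                    stacklevel=2,
                )
        for rec in self.records:
            if rec.id in tags:
                rec.locus = tags[rec.id]


@dataclass
class Alignment:
    """Rectangular alignment over the amino-acid alphabet plus gap.

    Every row degapped reproduces the residues of the corresponding input
    sequence exactly; no column is all-gap.
    """

    ids: list[str]
    rows: list[str]
    descriptions: list[str] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise SequenceFormatError("ids and rows differ in count")
        if len(set(self.ids)) != len(self.ids):
            raise SequenceFormatError("duplicate identifier in alignment")
        if not self.rows:
            raise SequenceFormatError("empty alignment")
        length = len(self.rows[0])
        for seq_id, row in zip(self.ids, self.rows):
            if len(row) != length:
                raise SequenceFormatError(
                    f"row {seq_id!r} has length {len(row)}, expected {length}"
                )
            bad = set(row) - RESIDUE_ALPHABET - {GAP}
            if bad:
                raise SequenceFormatError(
                    f"row {seq_id!r} contains illegal characters {sorted(bad)!r}"
                )
        for col in range(length):
            if all(row[col] == GAP for row in self.rows):
                raise SequenceFormatError(f"column {col} is all-gap")

    @property
    def length(self) -> int:
        """Alignment length (column count)."""
        return len(self.rows[0])

    @property
    def m(self) -> int:
        return len(self.rows)

    def row(self, seq_id: str) -> str:
        return self.rows[self.ids.index(seq_id)]

    def ungapped_lengths(self) -> dict[str, int]:
        """Residue count per sequence (the l_i of the score definitions)."""
        return {seq_id: len(row) - row.count(GAP)
                for seq_id, row in zip(self.ids, self.rows)}

    def degapped(self) -> SequenceSet:
        return SequenceSet([
            SequenceRecord(seq_id, row.replace(GAP, ""),
                           description=(self.descriptions[i]
                                        if self.descriptions else None))
            for i, (seq_id, row) in enumerate(zip(self.ids, self.rows))
        ])


def _clean(seq: str) -> str:
    return seq.upper().replace(".", GAP)


def read_fasta(path: str | Path, aligned: bool = False) -> SequenceSet | Alignment:
    """Read a FASTA file as an unaligned SequenceSet or an Alignment.

    Parameters
    ----------
    path : path-like
        FASTA file, aligned (equal row lengths, ``-``/``.`` gaps) or not.
    aligned : bool
        When True the records must form a rectangular alignment and an
        :class:`Alignment` is returned; otherwise gap characters are
        rejected and a :class:`SequenceSet` is returned.
    """
    path = Path(path)
    ids: list[str] = []
    seqs: list[str] = []
    descriptions: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        descriptions.append(rec.description)
        seqs.append(_clean(str(rec.seq)))
    if not ids:
        raise SequenceFormatError(f"no FASTA records in {path}")
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise SequenceFormatError(f"duplicate identifiers {dup!r} in {path}")
    if aligned:
        lengths = {len(s) for s in seqs}
        if len(lengths) != 1:
            raise SequenceFormatError(
                f"aligned input {path} has ragged lengths {sorted(lengths)}"
            )
        return Alignment(ids, seqs, descriptions=descriptions)
    records = []
    for seq_id, seq, desc in zip(ids, seqs, descriptions):
        if GAP in seq:
            raise SequenceFormatError(
                f"gap character in unaligned input sequence {seq_id!r}"
            )
        records.append(SequenceRecord(seq_id, seq, description=desc))
    return SequenceSet(records)


def read_locus_tags(path: str | Path) -> dict[str, str]:
    """Read the two-column locus-tag table mapping sequence id -> gene id.

    The first column is the sequence identifier (a leading ``>`` is
    tolerated and stripped), the second the gene identifier.  Sequences
    absent from the file are singleton loci: they simply stay unmapped.
    """
    mapping: dict[str, str] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) < 2:
                raise SequenceFormatError(
                    f"{path}:{lineno}: expected two whitespace-separated "
                    f"columns, got {line.rstrip()!r}"
                )
            seq_id = fields[0].lstrip(">")
            gene_id = fields[1]
            if seq_id in mapping and mapping[seq_id] != gene_id:
                raise SequenceFormatError(
                    f"{path}:{lineno}: sequence {seq_id!r} mapped to both "
                    f"{mapping[seq_id]!r} and {gene_id!r}"
                )
            mapping[seq_id] = gene_id
    return mapping


def _fasta_lines(header: str, seq: str, width: int = 60) -> Iterable[str]:
    yield f">{header}\n"
    for start in range(0, len(seq), width):
        yield seq[start:start + width] + "\n"


def write_fasta(obj: SequenceSet | Alignment, path: str | Path) -> None:
    """Write a SequenceSet or Alignment in FASTA, preserving headers."""
    with open(path, "w") as handle:
        if isinstance(obj, Alignment):
            descs = obj.descriptions or obj.ids
            for seq_id, desc, row in zip(obj.ids, descs, obj.rows):
                handle.writelines(_fasta_lines(desc or seq_id, row))
        else:
            for rec in obj:
                handle.writelines(_fasta_lines(rec.description or rec.id,
                                               rec.residues))


def write_scores(scores, path: str | Path) -> None:
    """Write the per-sequence score file: ``id<TAB>score`` to 6 decimals."""
    with open(path, "w") as handle:
        for seq_id in scores.ids:
            handle.write(f"{seq_id}\t{scores.scores[seq_id]:.6f}\n")


def write_outputs(
    out_prefix: str | Path,
    reference: Alignment,
    scores,
    selection: Mapping[str, str] | None = None,
    seqs: SequenceSet | None = None,
    locus_supplied: bool = False,
) -> dict[str, Path]:
    """Write the run's output files next to ``out_prefix``.

    Always writes ``<prefix>.aln`` (the reference alignment) and the score
    file (``<prefix>.scores``, or ``<prefix>.DistanceScore`` for the
    distance-score variants).  When a locus map was supplied, also writes
    ``<prefix>_filtered.fasta`` holding exactly one record per locus, in
    input order, with the original headers.

    Returns a mapping of logical name -> written path.
    """
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    aln_path = out_prefix.with_name(out_prefix.name + ".aln")
    write_fasta(reference, aln_path)
    written["alignment"] = aln_path

    suffix = ".DistanceScore" if scores.variant in ("ds", "ds_wot") else ".scores"
    score_path = out_prefix.with_name(out_prefix.name + suffix)
    write_scores(scores, score_path)
    written["scores"] = score_path

    if locus_supplied and selection is not None and seqs is not None:
        keep = set(selection.values())
        filtered = SequenceSet([rec for rec in seqs if rec.id in keep])
        filt_path = out_prefix.with_name(out_prefix.name + "_filtered.fasta")
        write_fasta(filtered, filt_path)
        written["filtered"] = filt_path
    return written
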