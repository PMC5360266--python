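"""Multiple-sequence-alignment adapters.

External programs (clustalo, mafft, muscle) are driven through a subprocess
contract: input FASTA, optional guide-tree file in the tool's own dialect,
output FASTA captured and reordered back to input order.  A deterministic
built-in progressive aligner ("mock") makes the whole pipeline testable
with zero external binaries: it merges profiles in the post-order of the
guide tree using BLOSUM62 and affine gap costs, so different guide trees
can produce different alignments — exactly the sensitivity the perturbed
alignments rely on.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .bionj import TreeNode, bionj_tree, to_newick
from .distmodels import AA_ORDER, GAP_CODE, X_CODE, DistanceMatrix, p_distance
from .seqio import Alignment, SequenceSet, read_fasta, write_fasta

GAP_OPEN = 10.0
GAP_EXTEND = 1.0
#: branch lengths clamped to this before guide-tree export
MIN_BRANCH = 1e-8

ALIGNER_NAMES = ("clustalo", "mafft", "muscle", "mock")


class AlignerError(RuntimeError):
    pass


class AlignerNotFoundError(AlignerError):
    pass


@dataclass(frozen=True)
class AlignerSpec:
    """Which alignment program to use and how to invoke it."""

    name: str = "mock"
    executable: str | None = None
    extra_options: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.name not in ALIGNER_NAMES:
            raise ValueError(f"unknown aligner {self.name!r}; "
                             f"choose from {ALIGNER_NAMES}")

    def resolve(self) -> str | None:
        """Path of the external binary, or None for the built-in aligner."""
        if self.name == "mock":
            return None
        exe = self.executable or self.name
        path = shutil.which(exe)
        if path is None:
            raise AlignerNotFoundError(
                f"aligner executable {exe!r} not found on PATH"
            )
        return path


def ensure_available(spec: AlignerSpec) -> None:
    """Probe the aligner before a run starts; raises if not invocable."""
    spec.resolve()


# --- built-in progressive aligner -------------------------------------------

_CODE_TO_CHAR = AA_ORDER + "-X"


def _score_table() -> np.ndarray:
    from Bio.Align import substitution_matrices

    blosum = substitution_matrices.load("BLOSUM62")
    table = np.zeros((22, 22))
    for i, x in enumerate(AA_ORDER):
        for j, y in enumerate(AA_ORDER):
            table[i, j] = blosum[x, y]
    # X scores 0 against everything; gap-in-profile columns score 0
    return table


_SCORE_TABLE: np.ndarray | None = None


def _get_score_table() -> np.ndarray:
    global _SCORE_TABLE
    if _SCORE_TABLE is None:
        _SCORE_TABLE = _score_table()
    return _SCORE_TABLE


class _Profile:
    __slots__ = ("ids", "codes")

    def __init__(self, ids: list[str], codes: np.ndarray):
        self.ids = ids
        self.codes = codes  # (n_rows, n_cols) int8

    @classmethod
    def from_sequence(cls, seq_id: str, residues: str) -> "_Profile":
        codes = np.array([[_CODE_TO_CHAR.index(ch) if ch in _CODE_TO_CHAR
                           else X_CODE for ch in residues]], dtype=np.int8)
        return cls([seq_id], codes)

    def counts(self) -> np.ndarray:
        n_rows, n_cols = self.codes.shape
        out = np.zeros((n_cols, 22))
        for row in self.codes:
            np.add.at(out, (np.arange(n_cols), row), 1.0)
        return out


def _pair_scores(a: _Profile, b: _Profile) -> np.ndarray:
    """Column-vs-column sum-of-pairs scores, averaged per row pair."""
    ca, cb = a.counts(), b.counts()
    raw = ca @ _get_score_table() @ cb.T
    return raw / (a.codes.shape[0] * b.codes.shape[0])


_NEG = -1e30


def _affine_align(a: _Profile, b: _Profile) -> _Profile:
    """Global profile-profile alignment, affine gaps, deterministic traceback.

    Gap costs are kept constant across columns so residue homology alone
    anchors the placement of event regions; per-column cost schedules were
    tried and found to let gap blocks drift with merge order, blurring the
    very stability signal the perturbation scores measure.
    """
    s = _pair_scores(a, b)
    la, lb = s.shape
    open_e = np.full(lb, GAP_OPEN)  # opening a gap in A opposite B column j
    open_f = np.full(la, GAP_OPEN)  # opening a gap in B opposite A column i
    M = np.full((la + 1, lb + 1), _NEG)
    E = np.full((la + 1, lb + 1), _NEG)  # gap in A (consumes a B column)
    F = np.full((la + 1, lb + 1), _NEG)  # gap in B (consumes an A column)
    M[0, 0] = 0.0
    j_idx = np.arange(1, lb + 1)
    E[0, 1:] = -open_e[0] - GAP_EXTEND * j_idx
    for i in range(1, la + 1):
        F[i, :] = np.maximum(np.maximum(M[i - 1, :], E[i - 1, :]) - open_f[i - 1],
                             F[i - 1, :]) - GAP_EXTEND
        best_prev = np.maximum(np.maximum(M[i - 1, :-1], E[i - 1, :-1]),
                               F[i - 1, :-1])
        M[i, 1:] = s[i - 1, :] + best_prev
        # E within-row recurrence unrolled as a prefix maximum:
        # E[i,j] = max_k (max(M,F)[i,k] - open_e[k] + ext*k) - ext*j
        mf = np.maximum(M[i, :], F[i, :])
        run = np.maximum.accumulate(
            mf[:-1] - open_e + GAP_EXTEND * np.arange(lb))
        E[i, 1:] = run - GAP_EXTEND * (1 + np.arange(lb))

    ops: list[tuple[str, int, int]] = []
    i, j = la, lb
    state = "MEF"[int(np.argmax([M[i, j], E[i, j], F[i, j]]))]
    tol = 1e-9
    while i > 0 or j > 0:
        if i == 0:
            state = "E"
        elif j == 0:
            state = "F"
        if state == "M":
            ops.append(("M", i - 1, j - 1))
            cands = (M[i - 1, j - 1], E[i - 1, j - 1], F[i - 1, j - 1])
            state = "MEF"[int(np.argmax(cands))]
            i, j = i - 1, j - 1
        elif state == "E":
            ops.append(("E", -1, j - 1))
            c_m = M[i, j - 1] - open_e[j - 1] - GAP_EXTEND
            c_e = E[i, j - 1] - GAP_EXTEND
            c_f = F[i, j - 1] - open_e[j - 1] - GAP_EXTEND
            best = max(c_m, c_e, c_f)
            state = "M" if c_m >= best - tol else ("E" if c_e >= best - tol else "F")
            j -= 1
        else:
            ops.append(("F", i - 1, -1))
            c_m = M[i - 1, j] - open_f[i - 1] - GAP_EXTEND
            c_e = E[i - 1, j] - open_f[i - 1] - GAP_EXTEND
            c_f = F[i - 1, j] - GAP_EXTEND
            best = max(c_m, c_e, c_f)
            state = "M" if c_m >= best - tol else ("E" if c_e >= best - tol else "F")
            i -= 1
    ops.reverse()

    n_cols = len(ops)
    na, nb = a.codes.shape[0], b.codes.shape[0]
    merged = np.full((na + nb, n_cols), GAP_CODE, dtype=np.int8)
    for col, (op, ia, jb) in enumerate(ops):
        if op in ("M", "F"):
            merged[:na, col] = a.codes[:, ia]
        if op in ("M", "E"):
            merged[na:, col] = b.codes[:, jb]
    return _Profile(a.ids + b.ids, merged)


def _default_guide_tree(seqs: SequenceSet) -> TreeNode:
    """Guide tree for the built-in aligner from pairwise alignment p-distances."""
    records = list(seqs)
    m = len(records)
    d = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            prof = _affine_align(
                _Profile.from_sequence(records[i].id, records[i].residues),
                _Profile.from_sequence(records[j].id, records[j].residues),
            )
            rows = ["".join(_CODE_TO_CHAR[c] for c in prof.codes[k])
                    for k in range(2)]
            d[i, j] = d[j, i] = p_distance(rows[0], rows[1])
    return bionj_tree(DistanceMatrix([rec.id for rec in records], d))


def _mock_align(seqs: SequenceSet, tree: TreeNode | None) -> Alignment:
    records = {rec.id: rec for rec in seqs}
    if len(records) == 1:
        raise AlignerError("alignment requires at least 2 sequences")
    if tree is None and len(records) >= 3:
        tree = _default_guide_tree(seqs)

    if tree is None:  # two sequences: single pairwise merge
        ids = list(records)
        profile = _affine_align(
            _Profile.from_sequence(ids[0], records[ids[0]].residues),
            _Profile.from_sequence(ids[1], records[ids[1]].residues),
        )
    else:
        leaf_names = set(tree.leaf_names())
        if leaf_names != set(records):
            raise AlignerError(
                "guide-tree leaves do not match the sequence identifiers: "
                f"missing {sorted(set(records) - leaf_names)}, "
                f"extra {sorted(leaf_names - set(records))}"
            )
        stack: dict[int, _Profile] = {}
        for node in tree.postorder():
            if node.is_leaf:
                stack[id(node)] = _Profile.from_sequence(
                    node.name, records[node.name].residues)
            else:
                parts = [stack.pop(id(child)) for child in node.children]
                profile = parts[0]
                for part in parts[1:]:
                    profile = _affine_align(profile, part)
                stack[id(node)] = profile
        profile = stack.popitem()[1]

    order = {seq_id: pos for pos, seq_id in enumerate(profile.ids)}
    rows = []
    for rec in seqs:
        row = "".join(_CODE_TO_CHAR[c] for c in profile.codes[order[rec.id]])
        rows.append(row)
    descriptions = [rec.description for rec in seqs]
    return Alignment([rec.id for rec in seqs], rows, descriptions=descriptions)


# --- external tool adapters --------------------------------------------------

def _clamped_newick(tree: TreeNode) -> str:
    for node in tree.postorder():
        if node.parent is not None and node.length < MIN_BRANCH:
            node.length = MIN_BRANCH
    return to_newick(tree)


def _binarise(tree: TreeNode) -> TreeNode:
    """Resolve multifurcations left-to-right with zero-length internal edges."""
    for node in list(tree.postorder()):
        while len(node.children) > 2:
            left, right = node.children[0], node.children[1]
            inner = TreeNode(length=MIN_BRANCH)
            inner.add_child(left)
            inner.add_child(right)
            node.children = [inner] + node.children[2:]
            inner.parent = node
    return tree


def _mafft_treein(tree: TreeNode, order: dict[str, int]) -> str:
    """Convert a guide tree to mafft's merge-instruction (treein) format.

    Each line merges two clusters identified by the 1-based input index of
    their smallest member, with the two branch lengths.
    """
    tree = _binarise(tree)
    lines: list[str] = []
    rep: dict[int, int] = {}
    for node in tree.postorder():
        if node.is_leaf:
            rep[id(node)] = order[node.name] + 1
        elif len(node.children) == 1:
            rep[id(node)] = rep.pop(id(node.children[0]))
        else:
            a, b = node.children
            ra, rb = rep.pop(id(a)), rep.pop(id(b))
            la = max(a.length, MIN_BRANCH)
            lb = max(b.length, MIN_BRANCH)
            first, second = sorted((ra, rb))
            lines.append(f"{first:5d} {second:5d} {la:10.5f} {lb:10.5f}")
            rep[id(node)] = first
    return "\n".join(lines) + "\n"


def _run_external(seqs: SequenceSet, spec: AlignerSpec, tree: TreeNode | None,
                  workdir: str | None) -> Alignment:
    exe = spec.resolve()
    tmp_ctx = tempfile.TemporaryDirectory() if workdir is None else None
    run_dir = Path(tmp_ctx.name) if tmp_ctx else Path(workdir)
    run_dir.mkdir(parents=True, exist_ok=True)
    try:
        in_fasta = run_dir / "input.fasta"
        # bare ids as headers so the output maps back unambiguously
        write_fasta(SequenceSet([type(rec)(rec.id, rec.residues)
                                 for rec in seqs]), in_fasta)
        out_fasta = run_dir / "output.fasta"
        cmd = [exe]
        if spec.name == "mafft":
            if tree is not None:
                tree_file = run_dir / "treein"
                order = {rec.id: i for i, rec in enumerate(seqs)}
                tree_file.write_text(_mafft_treein(tree, order))
                cmd += ["--treein", str(tree_file)]
            cmd += ["--auto", "--anysymbol", *spec.extra_options, str(in_fasta)]
        elif spec.name == "clustalo":
            cmd += ["-i", str(in_fasta), "--outfmt=fasta", "--force",
                    "-o", str(out_fasta), *spec.extra_options]
            if tree is not None:
                tree_file = run_dir / "guide.nwk"
                tree_file.write_text(_clamped_newick(tree) + "\n")
                cmd += [f"--guidetree-in={tree_file}"]
        else:  # muscle
            cmd += ["-in", str(in_fasta), "-out", str(out_fasta),
                    *spec.extra_options]
            if tree is not None:
                tree_file = run_dir / "guide.nwk"
                tree_file.write_text(_clamped_newick(tree) + "\n")
                cmd += ["-usetree_nowarn", str(tree_file)]

        result = subprocess.run(cmd, capture_output=True, text=True)
        if result.returncode != 0:
            raise AlignerError(
                f"{spec.name} exited with status {result.returncode}: "
                f"{result.stderr.strip()[-500:]}"
            )
        if spec.name == "mafft":
            out_fasta.write_text(result.stdout)
        aligned = read_fasta(out_fasta, aligned=True)
        return _restore_order(seqs, aligned)
    finally:
        if tmp_ctx:
            tmp_ctx.cleanup()


def _restore_order(seqs: SequenceSet, aligned: Alignment) -> Alignment:
    if set(aligned.ids) != {rec.id for rec in seqs}:
        raise AlignerError("aligner output identifiers do not match the input")
    row_of = dict(zip(aligned.ids, aligned.rows))
    rows = []
    for rec in seqs:
        row = row_of[rec.id]
        if row.replace("-", "") != rec.residues:
            raise AlignerError(
                f"aligner altered the residues of sequence {rec.id!r}"
            )
        rows.append(row)
    return Alignment([rec.id for rec in seqs], rows,
                     descriptions=[rec.description for rec in seqs])


# --- public API ---------------------------------------------------------------

def align(seqs: SequenceSet, spec: AlignerSpec,
          workdir: str | None = None) -> Alignment:
    """Align a SequenceSet from scratch (step-1 reference alignment)."""
    if len(seqs) < 2:
        raise AlignerError("alignment requires at least 2 sequences")
    if spec.name == "mock":
        return _mock_align(seqs, None)
    return _run_external(seqs, spec, None, workdir)


def align_with_guide_tree(seqs: SequenceSet, tree: TreeNode, spec: AlignerSpec,
                          workdir: str | None = None) -> Alignment:
    """Realign a SequenceSet constrained by a guide tree (step-2 realignment)."""
    if len(seqs) < 2:
        raise AlignerError("alignment requires at least 2 sequences")
    if set(tree.leaf_names()) != {rec.id for rec in seqs}:
        raise AlignerError("guide-tree leaf set differs from the sequence ids")
    if spec.name == "mock":
        return _mock_align(seqs, tree)
    return _run_external(seqs, spec, tree, workdir)
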