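"""Synthetic gene families with known canonical isoforms, plus brute-force
oracles, so the whole pipeline is testable without downloads or binaries.

A family is one canonical protein evolved along a random species tree
under a uniform (Poisson) substitution process; each species contributes
one gene, and a configurable fraction of genes additionally contribute
alternative isoforms derived from the canonical sequence by splicing-like
events: exon skipping (a contiguous block deleted, with novel residues at
the splice junction where the joined exons split a codon), intron
retention (a low-complexity compositionally biased block inserted, the
signature of translated intronic sequence) or truncation (a prefix or
suffix removed).  The
truth map records the canonical isoform of every gene, and the canonical's
transcript index is randomised so identifier order carries no signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .bionj import TreeNode
from .seqio import AMINO_ACIDS, SequenceRecord, SequenceSet, write_fasta

DEFAULT_EVENT_MIX = {"exon_skip": 0.5, "intron_retention": 0.5,
                     "truncation": 0.0}

#: event size ranges, as fractions of the canonical length
EXON_SKIP_SPAN = (0.10, 0.40)
INTRON_RETENTION_SPAN = (0.10, 0.40)
TRUNCATION_SPAN = (0.20, 0.60)

#: per-edge branch lengths of the simulated species tree (substitutions/site);
#: leaf-to-leaf paths then span roughly 0.15-0.5, the divergence regime of
#: similarity-curated homolog families
BRANCH_LENGTH_RANGE = (0.02, 0.12)


@dataclass
class SyntheticFamily:
    species_tree: TreeNode
    sequences: SequenceSet
    truth: dict[str, str]            # gene id -> canonical sequence id
    events: dict[str, str] = field(default_factory=dict)  # seq id -> event

    def locus_map(self) -> dict[str, str]:
        return self.sequences.locus_map()

    def isoform_genes(self) -> list[str]:
        counts: dict[str, int] = {}
        for rec in self.sequences:
            gene = rec.locus or rec.id
            counts[gene] = counts.get(gene, 0) + 1
        return [gene for gene, n in counts.items() if n >= 2]


def _random_tree(n_leaves: int, rng: np.random.Generator) -> TreeNode:
    """Random topology by repeated random joins; lengths U[0.02, 0.12]."""
    nodes = [TreeNode(name=f"sp{i + 1:02d}",
                      length=float(rng.uniform(*BRANCH_LENGTH_RANGE)))
             for i in range(n_leaves)]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = TreeNode(length=float(rng.uniform(*BRANCH_LENGTH_RANGE)))
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)]
        nodes.append(parent)
    root = TreeNode()
    for node in nodes:
        root.add_child(node)
    return root


def _evolve(parent_seq: np.ndarray, t: float,
            rng: np.random.Generator) -> np.ndarray:
    """Uniform (Poisson) substitutions: each site changes w.p. 1 - e^-t."""
    child = parent_seq.copy()
    hit = rng.random(len(child)) < 1.0 - np.exp(-t)
    if hit.any():
        shifts = rng.integers(1, 20, size=int(hit.sum()))
        child[hit] = (child[hit] + shifts) % 20
    return child


def _apply_event(canonical: str, event: str, rng: np.random.Generator) -> str:
    n = len(canonical)
    if event == "exon_skip":
        span = int(round(n * rng.uniform(*EXON_SKIP_SPAN)))
        span = max(1, min(span, n - 1))
        start = int(rng.integers(0, n - span + 1))
        skipped = canonical[:start] + canonical[start + span:]
        # splice junctions split codons: the joined boundary gains novel residues
        out = list(skipped)
        for offset in (0, 1):
            pos = start - 1 + offset
            if 0 <= pos < len(out):
                out[pos] = AMINO_ACIDS[int(rng.integers(0, 20))]
        return "".join(out)
    if event == "intron_retention":
        span = int(round(n * rng.uniform(*INTRON_RETENTION_SPAN)))
        span = max(1, span)
        start = int(rng.integers(0, n + 1))
        # intron-derived peptide: low-complexity, compositionally biased
        alphabet = rng.choice(20, size=8, replace=False)
        weights = rng.dirichlet(np.full(8, 0.6))
        insert = "".join(AMINO_ACIDS[alphabet[c]]
                         for c in rng.choice(8, size=span, p=weights))
        return canonical[:start] + insert + canonical[start:]
    if event == "truncation":
        span = int(round(n * rng.uniform(*TRUNCATION_SPAN)))
        span = max(1, min(span, n - 1))
        if rng.random() < 0.5:
            return canonical[span:]
        return canonical[:-span]
    raise ValueError(f"unknown event {event!r}")


def simulate_family(n_species: int = 8, seq_length: int = 120,
                    isoform_rate: float = 0.3,
                    event_mix: dict[str, float] | None = None,
                    seed: int = 0) -> SyntheticFamily:
    """Simulate one gene family with known canonical isoforms.

    Parameters
    ----------
    n_species : int
        Number of species (= genes); at least 4.
    seq_length : int
        Canonical protein length at the root; at least 60.
    isoform_rate : float
        Probability that a gene carries alternative isoforms.
    event_mix : dict, optional
        Relative weights of the splicing-like events; defaults to an even
        exon-skip / intron-retention mix (truncation off, enable explicitly
        for partial-sequence scenarios).
    seed : int
        Fully determines the family.
    """
    if n_species < 4:
        raise ValueError("need at least 4 species")
    if seq_length < 60:
        raise ValueError("need a canonical length of at least 60")
    if not 0.0 <= isoform_rate <= 1.0:
        raise ValueError("isoform_rate must lie in [0, 1]")
    mix = dict(DEFAULT_EVENT_MIX if event_mix is None else event_mix)
    if any(w < 0 for w in mix.values()) or sum(mix.values()) <= 0:
        raise ValueError("event_mix weights must be non-negative, not all zero")
    names = list(mix)
    weights = np.array([mix[name] for name in names], dtype=float)
    weights /= weights.sum()

    rng = np.random.default_rng(seed)
    tree = _random_tree(n_species, rng)
    root_seq = rng.integers(0, 20, size=seq_length)

    leaf_seqs: dict[str, str] = {}

    def descend(node: TreeNode, seq: np.ndarray) -> None:
        for child in node.children:
            child_seq = _evolve(seq, child.length, rng)
            if child.is_leaf:
                leaf_seqs[child.name] = "".join(AMINO_ACIDS[c]
                                                for c in child_seq)
            else:
                descend(child, child_seq)

    descend(tree, root_seq)

    records: list[SequenceRecord] = []
    truth: dict[str, str] = {}
    events: dict[str, str] = {}
    for species in sorted(leaf_seqs):
        gene = f"{species}_g"
        canonical = leaf_seqs[species]
        if rng.random() < isoform_rate:
            n_alt = int(rng.integers(1, 3))  # 1 or 2 alternative isoforms
            canon_slot = int(rng.integers(0, n_alt + 1))
            for slot in range(n_alt + 1):
                seq_id = f"{gene}_i{slot + 1}"
                if slot == canon_slot:
                    residues = canonical
                    truth[gene] = seq_id
                else:
                    event = str(rng.choice(names, p=weights))
                    residues = _apply_event(canonical, event, rng)
                    events[seq_id] = event
                records.append(SequenceRecord(seq_id, residues, locus=gene))
        else:
            seq_id = f"{gene}_i1"
            records.append(SequenceRecord(seq_id, canonical, locus=gene))
            truth[gene] = seq_id
    return SyntheticFamily(tree, SequenceSet(records), truth, events)


def write_family(family: SyntheticFamily, directory: str | Path,
                 prefix: str = "family") -> tuple[Path, Path]:
    """Write a family as FASTA plus locus-tag table (multi-isoform genes only)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    fasta = directory / f"{prefix}.fasta"
    write_fasta(family.sequences, fasta)
    tags = directory / f"{prefix}_locus_tags.txt"
    multi = set(family.isoform_genes())
    with open(tags, "w") as handle:
        for rec in family.sequences:
            if rec.locus in multi:
                handle.write(f">{rec.id} {rec.locus}\n")
    return fasta, tags


# --- independent oracles ------------------------------------------------------

def _column_of_residue(row: str, k: int) -> int:
    """Column (0-based) of the k-th (1-based) residue of an aligned row."""
    seen = 0
    for col, ch in enumerate(row):
        if ch != "-":
            seen += 1
            if seen == k:
                return col
    raise IndexError(k)


def _ordinal_at_column(row: str, col: int) -> int | None:
    """1-based residue ordinal of a row at a column, None for a gap."""
    if row[col] == "-":
        return None
    return col + 1 - row[:col + 1].count("-")


def sp_score_oracle(ref, perturbed, variant: str = "default"):
    """Literal triple-loop transcription of the SP score definitions.

    Independent of the scoring module: string scanning only, O(m^2 * l * n),
    intended for instances with m <= 8, l <= 50, n <= 5.
    """
    from .scoring import ScoreTable

    ids = list(ref.ids)
    m = len(ids)
    n = len(perturbed)
    ell = ref.length
    scores: dict[str, float] = {}
    for i in range(m):
        l_i = len(ref.rows[i]) - ref.rows[i].count("-")
        residue_means = []
        for k in range(1, l_i + 1):
            col = _column_of_residue(ref.rows[i], k)
            m_k = sum(1 for row in ref.rows if row[col] != "-")
            m_g = m - m_k
            per_replicate = []
            for b in range(n):
                pert = perturbed[b]
                pcol = _column_of_residue(pert.rows[i], k)
                if m_k == 1:
                    if variant == "gap":
                        per_replicate.append(-1.0 / (m_g if m_g else 1))
                    else:
                        per_replicate.append(1.0)
                    continue
                total = 0.0
                for j in range(m):
                    if j == i:
                        continue
                    ref_partner = _ordinal_at_column(ref.rows[j], col)
                    if ref_partner is None:
                        continue
                    pert_partner = _ordinal_at_column(pert.rows[j], pcol)
                    p_ijk = 1.0 if pert_partner == ref_partner else 0.0
                    if variant == "gap":
                        p_ijk /= m_g if m_g else 1
                    total += p_ijk
                per_replicate.append(total / (m_k - 1))
            residue_means.append(sum(per_replicate) / n)
        if variant == "short":
            scores[ids[i]] = sum(residue_means) / ell
        else:
            scores[ids[i]] = sum(residue_means) / l_i
    return ScoreTable(variant=variant, scores=scores, n=n)


def nj_oracle(D) -> TreeNode:
    """Textbook neighbor joining on dict-of-dicts; independent of bionj."""
    ids = list(D.ids)
    if len(ids) < 3:
        raise ValueError("need at least 3 taxa")
    import numpy as _np

    values = _np.asarray(D.values, dtype=float)
    dist = {a: {b: float(values[i, j]) for j, b in enumerate(ids)}
            for i, a in enumerate(ids)}
    nodes: dict[str, TreeNode] = {name: TreeNode(name=name) for name in ids}
    active = list(ids)
    counter = 0
    while len(active) > 3:
        r = len(active)
        sums = {a: sum(dist[a][b] for b in active if b != a) for a in active}
        best = None
        for x in range(r):
            for y in range(x + 1, r):
                a, b = active[x], active[y]
                q = (r - 2) * dist[a][b] - sums[a] - sums[b]
                if best is None or q < best[0]:
                    best = (q, a, b)
        _, a, b = best
        limb_a = 0.5 * dist[a][b] + (sums[a] - sums[b]) / (2 * (r - 2))
        limb_b = dist[a][b] - limb_a
        counter += 1
        new_name = f"__internal{counter}"
        parent = TreeNode()
        nodes[a].length = limb_a
        nodes[b].length = limb_b
        parent.add_child(nodes[a])
        parent.add_child(nodes[b])
        nodes[new_name] = parent
        dist[new_name] = {}
        for c in active:
            if c in (a, b):
                continue
            d_new = 0.5 * (dist[a][c] + dist[b][c] - dist[a][b])
            dist[new_name][c] = d_new
            dist[c][new_name] = d_new
        active = [c for c in active if c not in (a, b)] + [new_name]
    a, b, c = active
    la = 0.5 * (dist[a][b] + dist[a][c] - dist[b][c])
    lb = 0.5 * (dist[a][b] + dist[b][c] - dist[a][c])
    lc = 0.5 * (dist[a][c] + dist[b][c] - dist[a][b])
    root = TreeNode()
    for name, length in zip((a, b, c), (la, lb, lc)):
        nodes[name].length = length
        root.add_child(nodes[name])
    return root
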