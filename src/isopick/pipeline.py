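"""Orchestration of a full isoform-selection run.

A sum-of-pairs run has three steps: (1) build the reference alignment of
the whole input; (2) for each of n bootstrap replicates, resample the
reference alignment's columns with replacement, compute a distance matrix
under the chosen substitution model, infer a BioNJ guide tree and realign
the original sequences with it; (3) score every sequence against the n
perturbed alignments and keep the best-scoring isoform of each locus.
The distance-score variants skip the bootstrap entirely.

One master seed spawns an independent child random stream per replicate
index, so the worker-thread count never changes the results.
"""

from __future__ import annotations

import logging
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from . import seqio
from .aligners import AlignerSpec, align, align_with_guide_tree, ensure_available
from .bionj import TreeNode, bionj_tree
from .distmodels import ModelSpec, distance_matrix
from .scoring import (
    DS_VARIANTS,
    SP_VARIANTS,
    ScoreTable,
    distance_scores,
    select_per_locus,
    sp_scores,
)
from .seqio import Alignment, SequenceSet

logger = logging.getLogger(__name__)

#: -auto rule: fraction of columns that must exceed the gap threshold
AUTO_GAPPY_COLUMN_FRACTION = 0.35
#: -auto rule: gap proportion above which a column counts as gappy
AUTO_GAP_PROPORTION = 0.80
AUTO_MAX_SEQUENCES = 600
AUTO_MAX_COLUMNS = 10_000


@dataclass
class RunConfig:
    """Everything that determines a run (and hence its outputs)."""

    aligner: AlignerSpec = field(default_factory=AlignerSpec)
    model: ModelSpec = field(default_factory=ModelSpec)
    n: int = 30
    variant: str = "default"  # default | gap | short | ds | ds_wot | auto
    seed: int = 0
    threads: int = 1
    out_prefix: str | None = None
    keep_intermediates: bool = False

    def __post_init__(self) -> None:
        if self.variant not in SP_VARIANTS + DS_VARIANTS + ("auto",):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.variant in SP_VARIANTS and self.n < 1:
            raise ValueError("SP variants need at least one bootstrap replicate")
        if self.threads < 1:
            raise ValueError("threads must be >= 1")


@dataclass
class RunResult:
    scores: ScoreTable
    selection: dict[str, str]
    reference: Alignment
    variant: str


def bootstrap_replicate(aln: Alignment, rng: np.random.Generator) -> Alignment:
    """Resample the alignment's columns uniformly with replacement."""
    cols = rng.integers(0, aln.length, size=aln.length)
    rows = ["".join(row[c] for c in cols) for row in aln.rows]
    return Alignment(list(aln.ids), rows)


def tree_length(tree: TreeNode) -> float:
    """Sum of all branch lengths (minimum-evolution self-evaluation)."""
    return tree.tree_length()


def auto_mode(reference: Alignment, seqs: SequenceSet) -> str:
    """Pick a scoring variant from the dataset's shape.

    Strictly more than 35% of columns with strictly more than 80% gaps
    selects the gap variant; more than 600 sequences or more than 10000
    columns selects the distance-score variant; otherwise the default.
    """
    m = reference.m
    gap_counts = np.array([
        sum(1 for row in reference.rows if row[c] == "-")
        for c in range(reference.length)
    ])
    gappy_fraction = float((gap_counts / m > AUTO_GAP_PROPORTION).mean())
    if gappy_fraction > AUTO_GAPPY_COLUMN_FRACTION:
        return "gap"
    if seqs.m > AUTO_MAX_SEQUENCES or reference.length > AUTO_MAX_COLUMNS:
        return "ds"
    return "default"


def _reference_alignment(seqs: SequenceSet, cfg: RunConfig,
                         reference: Alignment | None) -> Alignment:
    if reference is not None:
        if list(reference.ids) != seqs.ids:
            raise ValueError("supplied reference alignment ids differ from input")
        return reference
    return align(seqs, cfg.aligner)


def _one_replicate(b: int, seed_seq: np.random.SeedSequence, seqs: SequenceSet,
                   reference: Alignment, cfg: RunConfig) -> Alignment:
    try:
        rng = np.random.default_rng(seed_seq)
        boot = bootstrap_replicate(reference, rng)
        if seqs.m >= 3:
            dm = distance_matrix(boot, cfg.model)
            guide = bionj_tree(dm)
            return align_with_guide_tree(seqs, guide, cfg.aligner)
        return align(seqs, cfg.aligner)
    except Exception as exc:  # surface the replicate index
        raise RuntimeError(f"bootstrap replicate {b + 1} failed: {exc}") from exc


def run_sp(seqs: SequenceSet, cfg: RunConfig,
           reference: Alignment | None = None) -> RunResult:
    """Full bootstrap sum-of-pairs run (default, gap or short variant)."""
    variant = cfg.variant if cfg.variant in SP_VARIANTS else "default"
    ensure_available(cfg.aligner)
    ref = _reference_alignment(seqs, cfg, reference)

    children = np.random.SeedSequence(cfg.seed).spawn(cfg.n)
    if cfg.threads > 1:
        with ThreadPoolExecutor(max_workers=cfg.threads) as pool:
            perturbed = list(pool.map(
                lambda args: _one_replicate(*args),
                [(b, children[b], seqs, ref, cfg) for b in range(cfg.n)],
            ))
    else:
        perturbed = [_one_replicate(b, children[b], seqs, ref, cfg)
                     for b in range(cfg.n)]

    scores = sp_scores(ref, perturbed, variant)
    locus_map = seqs.locus_map()
    selection = select_per_locus(scores, locus_map)
    _write(cfg, ref, scores, selection, seqs)
    return RunResult(scores, selection, ref, variant)


def run_ds(seqs: SequenceSet, cfg: RunConfig,
           reference: Alignment | None = None) -> RunResult:
    """Distance-score run: no bootstrap, selection by smallest mean distance."""
    variant = cfg.variant if cfg.variant in DS_VARIANTS else "ds"
    ensure_available(cfg.aligner)
    ref = _reference_alignment(seqs, cfg, reference)
    locus_map = seqs.locus_map()
    scores = distance_scores(ref, locus_map, wot=(variant == "ds_wot"))
    selection = select_per_locus(scores, locus_map)
    _write(cfg, ref, scores, selection, seqs)
    return RunResult(scores, selection, ref, variant)


def run(seqs: SequenceSet, cfg: RunConfig,
        reference: Alignment | None = None) -> RunResult:
    """Dispatch on the configured variant, resolving ``auto`` first."""
    if cfg.variant == "auto":
        ensure_available(cfg.aligner)
        ref = _reference_alignment(seqs, cfg, reference)
        chosen = auto_mode(ref, seqs)
        logger.info("auto mode selected the %r variant", chosen)
        cfg = replace(cfg, variant=chosen)
        reference = ref
    if cfg.variant in DS_VARIANTS:
        return run_ds(seqs, cfg, reference)
    return run_sp(seqs, cfg, reference)


def _write(cfg: RunConfig, ref: Alignment, scores: ScoreTable,
           selection: Mapping[str, str], seqs: SequenceSet) -> None:
    if cfg.out_prefix is None:
        return
    locus_supplied = any(rec.locus is not None for rec in seqs)
    seqio.write_outputs(cfg.out_prefix, ref, scores, dict(selection), seqs,
                        locus_supplied=locus_supplied)
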