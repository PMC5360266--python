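# Methods

## Problem and model

Eukaryotic homolog sets mix alternative protein isoforms of the same
genomic locus. `isopick` ranks the isoforms of each locus by alignment
robustness: a sequence whose residues keep the same pairing partners when
the alignment is rebuilt under perturbed guide trees is considered
reliable; one whose residues wander is not. The perturbation is a column
bootstrap of the reference alignment — resampling ℓ columns with
replacement, estimating pairwise distances from the resample, inferring a
BioNJ guide tree and realigning the original (full-length) sequences with
it. Because residues are tracked by ordinal (the *k*-th residue of
sequence *i*), alignments of different lengths are directly comparable.

Scores per sequence:

* default: S_i = mean over the sequence's own residues of the mean
  replicate agreement R_ik, with the convention that a residue alone in
  its reference column (m_k = 1) scores 1. Bounded in [0, 1].
* gap: every agreement divided by the gap count m_g of the reference
  column (m_g := 1 when there is no gap); a lone residue scores −1/m_g.
  The published rule fixes the lone-residue pair score at −1 but leaves
  its normalisation over an empty partner sum undefined; −1/m_g preserves
  the penalty's intent and degrades continuously to the no-gap case.
* short: the residue-score sum divided by ℓ rather than by the sequence
  length, so partial sequences cannot win on their few well-aligned
  residues alone.
* distance scores (DS): no bootstrap; S_i is the mean modified
  p-distance (gap = 21st state, double-gap columns excluded, columns with
  X excluded) to the isoform-free backbone Ω, or to all other sequences
  ("with other transcripts", WOT). Selection minimises. When Ω is a
  summation set, the mean is taken over the terms actually summed
  (j ∈ Ω, j ≠ i); the published notation is ambiguous on whether i
  itself is excluded, and excluding it is the only convention that keeps
  the score finite for backbone members.

Selection compares full-precision scores; exact ties go to the
lexicographically smallest identifier and are logged.

## Distance models

Closed forms on the observed proportion p: Poisson −ln(1−p), its Gamma
generalisation α[(1−p)^(−1/α) − 1] (α defaults to 1.0 when Gamma
correction is requested without a shape), Kimura's PAM approximation
−ln(1 − p − 0.2p²), and a Gamma–Poisson approximation of JTT distances
with shape 2.4 (configurable; the constant of the original approximation
is not published, so this default is declared, not inferred).

Matrix models (Dayhoff/PAM, JTT, WAG, LG) use pairwise maximum
likelihood: the reversible rate matrix Q = S·diag(π), normalised to one
expected substitution per site per unit time, is eigendecomposed through
its symmetrised form, and the log-likelihood Σ N_xy log(π_x P_xy(t)) over
comparable columns is maximised on t ∈ [10⁻⁶, 10] by bounded scalar
minimisation (tolerance 10⁻⁶). The exchangeabilities and frequencies are
the published model constants. BLOSUM62 is a score matrix, not a rate
matrix; it is inverted through its log-odds definition
s = 2·log₂(q/(π_x π_y)): the self-consistent background solves the linear
system Σ_y π_y 2^(s_xy/2) = 1, after which the odds matrix itself is the
exchangeability matrix. Gamma rate heterogeneity for matrix models mixes
the transition matrix over four equal-probability discrete categories
(mean-of-bin rates); the closed-form distance rescaling is deliberately
not reused there so the ML estimator stays coherent. The implementation
was cross-checked against an independent ML-distance implementation (the
phangorn R package) and agrees to well under 1% on simulated pairs.

Saturation: any distance at the configurable ceiling (default 10
substitutions/site) is flagged saturated; ML optima within 10⁻³ of the
ceiling are snapped to it. Kimura's form saturates at
1 − p − 0.2p² ≤ 0 (p ≈ 0.854).

## Tree inference

BioNJ agglomerates with the classical NJ selection criterion
Q_ij = (r−2)d_ij − R_i − R_j and NJ branch lengths, but reduces the
matrix with the variance-minimising weight
λ = ½ + Σ_k(v_jk − v_ik) / (2(r−2)v_ij), clamped to [0, 1], with
variances initialised proportional to the distances and reduced as
v_uk = λv_ik + (1−λ)v_jk − λ(1−λ)v_ij. A zero-variance denominator sets
λ = ½, which is exactly classical NJ. Ties on the selection criterion
break on the lowest (row, column) pair in current matrix order, making
the whole inference deterministic. Negative branch lengths from the NJ
formulas are kept internally and clamped to 10⁻⁸ only on guide-tree
export, since some aligners reject non-positive lengths. On additive
matrices the inferred path lengths reproduce the input to < 10⁻⁹.

## Aligners

External aligners are driven through subprocess adapters (input FASTA,
guide tree in the tool's dialect — newick for clustalo and muscle,
merge-instruction format for mafft — output reordered to input order and
verified to degap back to the input residues). The built-in aligner is a
deterministic progressive profile merger over the guide tree's
post-order: column-vs-column sum-of-pairs scores under BLOSUM62
(vectorised as count-matrix products), global affine gaps (open 10,
extend 1), and a fixed-precedence traceback, so it is a pure function of
(sequences, tree) and bit-identical across runs. Gap costs are constant
across columns: occupancy-scaled (position-specific) gap costs were
evaluated and discarded because they let gap blocks drift with merge
order, injecting instability into well-anchored sequences and blurring
the signal the perturbation scores measure. Without a guide tree the
built-in aligner estimates one by BioNJ on pairwise alignment
p-distances. It is a test harness, not a competitive MSA method.

## Pipeline

One master seed spawns an independent child stream per bootstrap
replicate, so results are independent of the worker-thread count;
replicates are reduced in index order. Defaults: n = 30 replicates, the
Gamma–Poisson JTT closed form for bootstrap distance matrices, mafft as
aligner when its binary resolves, otherwise the built-in aligner. The
automatic mode applies strict inequalities (> 35% of columns > 80% gaps →
gap variant; > 600 sequences or > 10 000 columns → distance scores) and
never selects the short variant. Input already aligned (declared with
`--aligned`) skips the reference-alignment step. Outputs: the reference
alignment (`<prefix>.aln`), per-sequence scores to six decimals
(`<prefix>.scores`, or `<prefix>.DistanceScore` for distance modes), and,
when a locus map was supplied, `<prefix>_filtered.fasta` with exactly one
record per locus in input order.

## Synthetic data generator

`fixtures.simulate_family` evolves one canonical protein along a random
species tree (random joins; per-edge lengths uniform on [0.02, 0.12],
giving leaf-to-leaf divergences of roughly 0.15–0.5 substitutions/site —
the regime of similarity-curated homolog families) under a uniform
substitution process, then derives alternative isoforms per gene:

* exon skip — a contiguous block of 10–40% of the canonical deleted,
  with two novel residues at the junction (splice sites split codons);
* intron retention — a block of 10–40% inserted, drawn from a biased
  8-letter alphabet per insert, reproducing the low sequence complexity
  of translated intronic material;
* truncation — 20–60% removed from one end (off by default: partial
  sequences are a database-curation artifact, exercised explicitly in
  the short-variant scenarios).

The canonical's transcript index is randomised so identifier order
carries no information, and the truth map records it per gene.

What the generator deliberately does **not** emulate: real splice-site
grammar, proteome length distributions, cross-species conservation of
splicing events, and — most consequentially — isoform junk that
misaligns against *residues* rather than against gaps. On clean families
this has a measurable effect on what the bootstrap SP statistic can
resolve: an alternative isoform whose residues align exactly as robustly
as its canonical's ties with it (both score 1), and a private insert
occupies columns where every other sequence is gapped, so the m_k = 1
convention pins its residues at the maximum score. Canonical-isoform
recovery of the default SP pipeline on such data therefore reflects
junction-instability signal only (measured around 50–60% on the default
suite, against 10 families × 8 species at isoform rate 0.3 with n = 10),
while the distance-score mode — which compares against the isoform-free
backbone and counts length differences through the gap state — resolves
every gene on the same suite. Passing tests on this generator validate
the scoring machinery, its oracle equivalence, determinism and the
selection contracts; they do not certify recovery rates on real
proteomes, where isoform-specific material is far less cleanly gapped.
The tree-length self-check (sum of BioNJ branch lengths of the filtered
dataset, a minimum-evolution proxy) is likewise tie-prone here: a single
cleanly-gapped insert never enters the standard p-distance, so
longest-isoform and canonical selections often give equal-length trees.

## Numerical conventions

Residue ordinals are 1-based in every public interface; column indices
are 0-based and internal. `X` is a legal residue that never matches
anything and is excluded from all distance comparisons. `.` is read as a
gap, sequences are upper-cased on input, and identifiers are the FASTA
header up to the first whitespace (example identifiers contain `|`, so
splitting on it would be unsafe). Newick labels containing reserved
characters (including `|`) are quoted. Scores are printed to six
decimals; selection compares full precision.
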