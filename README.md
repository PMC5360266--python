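# isopick

Selection of one protein isoform per genomic locus before phylogenetic
reconstruction.

Homology searches against eukaryotic proteomes return every annotated
isoform of every gene. Keeping them all biases a phylogenetic analysis:
the redundant sequences distort alignment-trimming statistics, and
isoform-specific material (skipped exons, retained introns, frameshifted
tails) forces gap-riddled columns into the multiple sequence alignment.
The usual fallbacks — keep the longest isoform, or a random one — either
drag junk-carrying records into the dataset or throw information away
blindly. `isopick` instead scores every sequence by how *robustly* it
aligns, and keeps the best-scoring isoform of each locus.

## The score

Let *a* be the reference alignment of all *m* input sequences, ℓ its
length, and let *n* perturbed alignments be built by (1) resampling the
columns of *a* with replacement, (2) computing a distance matrix from the
resample under an amino-acid substitution model, (3) inferring a BioNJ
tree from it, and (4) realigning the original sequences with that tree as
guide tree. For residue *k* of sequence *i*, the pair score

&nbsp;&nbsp;&nbsp;&nbsp;R<sub>ik</sub>(b) = 1/(m<sub>k</sub>−1) · Σ<sub>j≠i</sub> p<sub>ijk</sub>

averages, over the m<sub>k</sub> sequences with a residue in that
reference column, the indicator p<sub>ijk</sub> that residues *k* of *i*
and *k′* of *j* face each other in both the reference and the perturbed
alignment *b* (a residue facing only gaps scores 1). Averaging over the
*n* replicates gives R<sub>ik</sub>, and the sum-of-pairs score of the
sequence is S<sub>i</sub> = (1/l<sub>i</sub>) Σ<sub>k</sub> R<sub>ik</sub>
∈ [0, 1]. Within each locus the isoform with the highest S<sub>i</sub> is
kept. Variants:

* `--gap` divides each p<sub>ijk</sub> by the number of gaps
  m<sub>g</sub> in the reference column (and scores a lone residue
  −1/m<sub>g</sub>), penalising sequences that force gaps on the
  alignment — suited to intron-retention / exon-skipping datasets;
* `--short` divides Σ R<sub>ik</sub> by ℓ instead of l<sub>i</sub>,
  penalising well-aligned but partial sequences;
* `--DS` skips the bootstrap entirely: S<sub>i</sub> is the mean
  *modified p-distance* (gap treated as a 21st character state) to the
  isoform-free backbone sequences, and the *smallest* score wins;
  `--WOT` compares against all sequences instead of the backbone;
* `--auto` picks `--gap` when more than 35% of columns are more than 80%
  gaps, `--DS` for more than 600 sequences or more than 10 000 columns,
  and the default otherwise.

Distance models for the bootstrap matrices: Poisson (optionally
Gamma-corrected), Kimura's PAM approximation, a Gamma–Poisson JTT
approximation, and maximum-likelihood distances under the Dayhoff/PAM,
JTT, WAG and LG matrices or a BLOSUM62-derived rate matrix.

## Worked example

Generate a small synthetic family (6 species, half the genes with
alternative isoforms) and run the default pipeline:

```bash
python - <<'PY'
from isopick.fixtures import simulate_family, write_family
fam = simulate_family(n_species=6, seq_length=90, isoform_rate=0.5, seed=42)
write_family(fam, "demo", prefix="family")
PY
isopick demo/family.fasta --locus-tags demo/family_locus_tags.txt \
        --aligner mock -n 10 --seed 1 --out demo/run/output
```

prints

```
variant: default
sequences scored: 10
loci selected: 6
```

and writes `output.aln` (the reference alignment), `output.scores` and
`output_filtered.fasta`. The score file starts

```
sp01_g_i1	0.997639
sp02_g_i1	0.994861
sp02_g_i2	0.992773
sp03_g_i1	0.995556
```

Each line is a sequence's S<sub>i</sub>: `sp02_g_i1` out-scores its
exon-skipped sibling `sp02_g_i2`, whose splice-junction region pairs less
consistently under the guide-tree perturbations, so only `sp02_g_i1`
survives into `output_filtered.fasta`, which holds exactly one record per
locus. With `--DS` the score file is named `output.DistanceScore` and the
*lowest* score per locus wins.

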