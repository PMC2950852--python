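# Methods

## The problem

When a plastid gene is transferred to the host nucleus (endosymbiotic
gene transfer, EGT), the copy suddenly finds itself under a different
mutational regime: plastid genomes drift toward A+T, nuclear genomes
toward G+C. Selection on the protein constrains most first and second
codon positions, but synonymous sites are free to record the new
pressure, so a recently transferred gene is compositionally intermediate
between its plastid paralog and long-resident nuclear homologues. The
same compositional convergence, however, corrupts phylogenetic
reconstruction: the transferred copy and unrelated genes of the same
compartment drift toward similar base (and, via weakly constrained
nonsynonymous sites, amino-acid) composition, and fast post-transfer
evolution puts the copy on a long branch — the classic preconditions for
long-branch attraction (LBA).

egtkit implements the statistics used to diagnose such a transfer
(composition profiles, synonymous-mutated-site composition, codon-aware
divergence, bipartite-presequence annotation) and the tree-building side
(saturation-filtered distances into neighbor joining, parsimony,
bootstrap), together with a generator of synthetic gene families with
known ground truth.

## Synonymous-mutated-site composition

Genes are compared within a protein-alignment-guided codon alignment
(`seq_io.back_align`), so codon homology is inherited from residue
homology. For every gene pair and codon column, the codon pair is
classified (`codon_compare.classify_codon_pair`) as identical /
synonymous-single / synonymous-multi / nonsynonymous. Only
**synonymous-single** pairs — same amino acid, exactly one differing
nucleotide — enter the mutated-site table: multi-hit codons have no
uniquely identifiable mutated site. For each record the nucleotide each
gene carries at the differing position is tallied per category (e.g.
genomic compartment), pooled across all pairs in the comparison design,
and summarised as an A+T fraction at mutated sites. Direction of
polarity is deliberately not inferred: no ancestral reconstruction is
attempted; the statistic asks only which base each lineage *now* holds
where a synonymous difference exists.

Ambiguity codes are excluded from every composition denominator.
Alignment columns containing a gap or X are masked out by default
(`MaskPolicy`); an optional per-column entropy threshold can flag
ambiguously aligned regions.

## Divergence and similarity

Nucleotide divergence between two homologues is counted over nucleotide
columns whose codons are both ungapped in the pairwise protein alignment
(substituted / aligned, both reported). Protein identity is the fraction
of identical both-ungapped columns; similarity is the fraction with a
strictly positive BLOSUM62 score (the "positives" convention). Pairwise
global alignments use biopython's `PairwiseAligner` with BLOSUM62, gap
open 10, gap extend 1; the first alignment in the aligner's
deterministic enumeration is used, and alignment parameters are echoed
in reports because counted substitutions depend on them.

## Bipartite presequence annotation

Diatom plastid-targeting presequences are annotated by explicit rules,
not trained predictors, so every decision is auditable:

- **Signal peptide**: a candidate cleavage boundary after residue *i*
  (default *i* in [12, 30]) requires mean Kyte–Doolittle hydrophobicity
  of residues 2..*i* above 1.6 and alanine at position *i* (the −1
  consensus). Candidates are ranked by motif evidence — phenylalanine
  at +1 and proline at +3 (the ASAF/AFAP-style motif) — then by
  hydrophobicity, then by shorter length.
- **Transit peptide**: the 15 residues after the cleavage site are
  scored for Ser+Thr fraction (bipartite verdict requires ≥ 0.20) and
  net charge (#KR − #DE).
- With a mature reference homologue, the N-terminal extension length is
  also measured from a global alignment, as an independent cross-check
  on the SP+TP annotation.

All thresholds are configuration surface, not claims; they were chosen
to bracket published diatom presequences and are reported with every
annotation. Coordinates are 1-based in all outputs.

## Saturation-filtered distances and trees

An empirical amino-acid model (LG by default, PAML-format matrices
accepted) is reduced to pair-type probabilities
P(i,j) ∝ π_i s_ij π_j, normalised over the 190 unordered residue pairs.
A differing residue pair is **frequent** if its probability reaches the
cutoff and **rare** otherwise; rare pairs are treated as saturated
(likely multiple superimposed substitutions). The default cutoff is the
lower quartile of the 190 pair-type probabilities — "rare" means the
improbable tail — and is deliberately exposed as a free parameter, since
the method is meant to be explored across cutoffs.

Distances are per-pair: for taxa a, b, columns whose (a, b) residue pair
is rare are excluded; p is the fraction of differing pairs among the
remaining effective sites, Poisson-corrected as d = −ln(1 − p).
Effective-site counts are reported per pair. At cutoff 0 the filter is
the identity and the distance reduces bitwise to the unfiltered
Poisson-corrected p-distance. A pair with zero effective sites is an
error naming the pair; p = 1 is capped at the resolution limit
1 − 1/(2n). Gamma rate correction is not offered: the target is
"conventional" NJ downstream of the filter.

Neighbor joining is implemented directly (Saitou–Nei; ties on Q broken
toward the lowest-index pair; negative branch estimates clamped to zero
at the end) because the library implementation available here proved
nondeterministic across calls, which would break the bootstrap and
idempotence contracts. It is exact on additive matrices and is
cross-checked in the tests against both a generate-from-tree oracle and
an independent library implementation.

Maximum parsimony uses Fitch scoring over bitmask state sets with
column-pattern compression; search is exhaustive through 8 taxa (all
co-optimal trees returned) and NNI hill-climbing from an NJ start above
that. Bootstrap is column resampling with replacement; support is the
percentage of replicate trees containing each split of the
point-estimate tree, seeded and reproducible. Robinson–Foulds distances
use dendropy's bipartition machinery, cross-checked against a direct
split-set comparison.

## The generator

`egt_simulator.simulate_egt` evolves a coding gene along a known tree.
Single-nucleotide changes are proposed uniformly and pass a
selection/bias filter:

- proposals creating a stop codon are rejected;
- synonymous proposals are accepted with probability `at_bias` when they
  increase A+T, `1 − at_bias` when they decrease it, 0.5 when neutral
  (A↔T, G↔C) — so the stationary composition at free synonymous sites
  approaches the compartment target;
- nonsynonymous proposals face the same tilt scaled by
  `p_nonsyn_accept` (purifying selection), normalised so an unbiased
  compartment accepts them at exactly `p_nonsyn_accept`.

Applying the compositional tilt to nonsynonymous proposals as well is a
deliberate design choice: compartment pressure acts on the mutational
input of all sites, and without it the translated alignment would carry
no compositional signal at all, making amino-acid-level artifacts
impossible to study. Every accepted synonymous change still leaves the
protein untouched (asserted via the mutation log).

Branch lengths are **expected accepted substitutions per codon**; each
branch draws its accepted count from a Poisson with that mean, so
divergence targets are directly dialable. The transfer event splits a
chosen branch at a time fraction, grafts a duplicate that switches
compartment (and optionally gains a planted SP+TP presequence), and the
grafted tree, per-gene compartments, full mutation log and presequence
coordinates are returned as ground truth. `replay_truth` re-applies the
log from the root and must reproduce every emitted sequence exactly. A
single seeded generator drives all draws; identical seeds give identical
FASTA bytes.

Default study conditions: 120-codon genes (a Psb28-sized protein); A+T
targets 0.70 (plastid), 0.45 (nuclear) at synonymous sites, mirroring
the compositional contrast observed between plastid and nuclear copies
of a recently transferred diatom gene; `p_nonsyn_accept` 0.15. Two named
scenarios are provided: `default_scenario` (recent transfer, moderate
divergence — used for composition, intermediacy and annotation
demonstrations) and `saturated_scenario` (deep divergences, weaker
selection, transfer early on the donor's terminal branch so the
transferred copy is the longest branch in the tree — the regime in which
conventional methods misplace it, used for the method-comparison
experiments).

### What the generator does not emulate

No indels (alignments are trivial, so alignment error is outside the
tested scope), no among-site rate heterogeneity, no codon-usage
selection beyond the AT/GC tilt, no recombination. Passing recovery
tests therefore show correctness of the statistics and tree machinery
under compositional bias, not robustness to alignment error or
rate-heterogeneous saturation. One consequence is worth stating plainly:
because saturation here is homogeneous across sites, the rare-pair
filter has no enriched target, and in the method-comparison experiments
filtered NJ performs on par with plain NJ (equal sister-placement rate,
slightly lower artifact-attachment rate and Robinson–Foulds distance)
rather than clearly rescuing the topology. On real proteins, where fast
sites concentrate saturation, the filter has more to remove.

## Recovery experiment

`recovery_experiment` replicates a scenario across seeds (100 by
default here) and scores each method (plain NJ, filtered NJ, MP)
against the truth: mean RF distance, the fraction of seeds placing the
transferred copy sister to its true paralog, and the fraction attaching
it inside the like-composition foreign clade. Problem sizes (9 taxa,
120 codons, 100 seeds) keep the full experiment under ~5 s.

## Pipeline

`pipeline.run_pipeline` wires the stages (compose → compare →
presequence → tree) with a single config whose every parameter is
echoed into the report, so each number is regenerable from inputs +
config + seed; reruns are byte-identical. Stage outputs are recomputed
on every run rather than cached: all stages complete in seconds at desk
scale, and a content-hash cache would add staleness risk without
measurable benefit. Failures on individual genes are logged as warnings
and skipped, not fatal. Multiple-sequence alignment construction is out
of scope: the pipeline consumes protein alignments (or the simulator's
indel-free families) and computes pairwise alignments only.

## Known limitations

- The masked-column policy is the strictest reproducible rule; it does
  not attempt to reproduce any particular manual alignment edit, so
  column counts on real datasets will differ from hand-curated ones.
- The mutated-site tabulation pools all pairs within a category;
  per-pair denominators can be recovered from the records table.
- Bayesian mixture-model inference (CAT-type) is not implemented; the
  tree module covers the distance/parsimony side only.
- Presequence annotation is sequence-level; it does not claim import
  competence.
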