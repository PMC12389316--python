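# Methods

`clsymine` re-implements, as a tested pipeline, the computational analysis
behind a profile-HMM survey of CLSY/DRD1-like chromatin remodelers in plant
proteomes: domain detection, family-specific model construction and
reduced-cutoff prospecting, distance-based phylogeny with clade assignment,
duplication typing with NG86 Ka/Ks and dating of soybean-style paralog
pairs, gene-structure summaries, and expression statistics. Every stage is
exercised end to end on synthetic data with known ground truth; this note
records the models, the parameters that matter, and the choices made where
the design was genuinely open.

## Profile HMMs and domain scanning

The scoring object is a classic profile HMM over the 20-residue alphabet:
match states with per-state emission distributions, insert states emitting
from the background, and per-node transition distributions (m→m/i/d, i→m/i,
d→m/d). Scoring is Viterbi in log2-odds bits against the background, with
Smith–Waterman-style local entry (uniform over the L match states, cost
log2(1/L)) and free exit from any match state; residues outside the hit
score zero under the null. This is conceptually HMMER's local mode, but it
is Viterbi bits against raw cutoffs — no forward scores, no E-value
calibration — and score parity with HMMER is deliberately not claimed. The
payoff is that the implementation is exactly checkable: a brute-force
enumeration of all local state paths reproduces every score to 1e-9 bits on
small instances (tested).

Proteome scanning applies per-model bit thresholds; the defaults for the
two Pfam-style domain models are 60 bits (SNF2) and 50 bits (Helicase C).
A protein's architecture class (both / SNF2_only / HelC_only / neither)
follows from which models hit it, and the partition identity
|SNF2_only| + |both| = |proteins with SNF2 hits| holds by construction.

Model I/O uses a documented subset of the HMMER3 text format (NAME, LENG,
ALPH amino, emission/transition lines as negative natural logs); COMPO and
annotation columns are ignored. Rows are renormalized on read to absorb the
5-decimal serialization.

## Family models and reduced-cutoff prospecting

Family-specific models are built from a training MSA of two-domain
proteins:

* **Column scores.** Information content of a column is the KL divergence
  (bits) of its gap-excluded, pseudocount-smoothed residue frequencies from
  the background (Laplace α = 0.5 per residue by default); when subgroup
  labels are supplied, a discrimination score is the mutual information
  between residue and label. These are the two standard
  information-theoretic readings of position-specific alignment scoring.
* **Blocks.** Maximal runs of columns with score ≥ 0.5 bits and gap
  fraction ≤ 0.3, kept if ≥ 20 columns long with mean ≥ 1.0 bits. The
  20-column minimum keeps every model long enough that its cutoff (below)
  stays far above what random sequence reaches by chance; shorter blocks
  produced cutoffs within a few bits of the noise tail.
* **Block HMMs.** One match state per block column with ≥ 50% residue
  occupancy; emissions are smoothed column frequencies; transitions are
  estimated from the observed gap structure with the same smoothing.
* **Validation and cutoffs.** A model "hits" a sequence when it scores
  ≥ 20 bits (10^6:1 odds over background — far above chance, far below any
  true positive). Validation succeeds when every known positive is hit by
  at least one model; each model records the minimum bit score over the
  positives it hits. Models hitting no positive are dropped with a warning.
* **Prospecting.** At reduced cutoff rc ∈ (0, 1], a protein passes when
  some model scores it at ≥ max(rc × that model's recorded cutoff,
  20 bits). The rc semantics (fraction of the minimum training-positive
  score) is this package's explicit definition; the absolute 20-bit floor
  guarantees that lowering rc can never dilute a short model's cutoff into
  the range random proteins reach. Candidates are monotone in rc by
  construction.

## Alignment

Pairwise alignment is global affine-gap DP (Gotoh) over BLOSUM62 with
open 11 / extend 1; a gap of length L costs open + (L−1)·extend, and
traceback ties break diagonal → up → left for reproducibility. The
progressive MSA uses a 3-mer count distance, a UPGMA guide tree
(scipy linkage), and affine profile–profile merging. No claim of
equivalence with MUSCLE or ClustalW is made; externally computed MSAs can
be supplied as aligned FASTA and bypass the module.

## Phylogeny

Distances are p or Poisson (−ln(1−p)) over columns where neither row is
gapped. Trees are neighbor joining (Q-criterion, lowest-index tie break),
negative branch lengths clamped to zero, midpoint-rooted; NJ recovers the
generating topology exactly on additive matrices (RF = 0, tested to 12
taxa). Bootstrap resamples columns with replacement; support of an internal
edge is the percentage of replicate trees containing the same unrooted
bipartition. Maximum-likelihood inference is out of scope; the alignment
can be exported in relaxed PHYLIP for an external ML program.

Clade assignment is root-independent: a reference clade is the smallest
bipartition side containing all of its anchors (midpoint rooting can land
inside a clade, so subtree-under-mrca semantics would be fragile), each
non-anchor leaf takes the label of the smallest side containing it, and
leaves in no anchor clade are outliers. Anchor sets whose clades mutually
contain each other's anchors are rejected as ambiguous. For synthetic
recovery tests, anchors are chosen as one leaf from each side of a
monophyletic group's root split, which guarantees the pair spans the group.

## Molecular evolution

Codon alignments are back-mapped from protein alignments; columns gapped in
either row are dropped and counted. Ka/Ks is Nei–Gojobori (1986):
synonymous site fractions per codon position are (# synonymous
single-nucleotide neighbors, stops excluded)/3, averaged over the two
sequences (S + N = 3 × codons); per-codon differences are averaged
uniformly over the minimal mutational pathways that avoid stop codons
(weights renormalized; if every pathway is blocked, all pathways are used
with stop steps counted as nonsynonymous); Jukes–Cantor correction
d = −(3/4)·ln(1 − (4/3)p) is applied per site class, with p ≥ 3/4 a
saturation error and Ka/Ks undefined when Ks = 0. An independent
pathway-enumeration oracle reproduces every quantity to 1e-12 on random
alignments. Biopython's NG86 agrees to ~0.02 at moderate divergence; the
residual difference is its convention of averaging over stop-passing
pathways rather than excluding them.

Duplication dates are T = Ks/(2λ) × 10⁻⁶ Mya with λ = 6.5 × 10⁻⁹
synonymous substitutions per site per year. Selection labels: purifying
(< 1), neutral (= 1 within 1e-9), positive (> 1).

Collinear blocks are rank-monotone chains of homolog pairs between two
chromosomes (both orientations), scored +1 per anchor and −0.1 per skipped
rank unit, with per-step rank gaps ≤ 3 and ≥ 3 anchors; maximal-scoring
non-overlapping chains are reported greedily. The gap limit of 3 keeps the
false-chain rate of a 100-pair random null on a 100×100 gene grid near 1%
(at gap 5 a random ≥5-anchor chain appears in roughly a third of nulls).
Duplication typing: a pair anchoring any block is WGD/segmental; otherwise
same-chromosome pairs are tandem (rank distance ≤ 1) or proximal (≤ 10);
everything else is dispersed.

## Gene structure

GFF3 is parsed with 1-based inclusive coordinates preserved; the
representative transcript is the mRNA with the longest total CDS; exon
lists follow transcription order (reverse genomic order on the minus
strand); gene length is the span of the gene feature including introns and
UTRs. Summaries report min/max/mode statistics per clade. The packaged
56-member characteristics table and the ten-pair paralog table are stored
verbatim as TSV (thousands separators preserved; decimal points only) and
every derivable cell — dates from Ks, ratios from Ka and Ks, selection
labels, structural ranges — is recomputed by `replay-tables`. Ratio cells
are compared at max(5e-4, one unit of the cell's printed precision): one
printed ratio (0.567) is a truncated 3-decimal cell whose exact value is
0.5677, so no comparison is made tighter than the table's own printing.

## Expression

TPM matrices are transformed entry-wise to log2(x + 1) (zeros map to zero;
a second transform is rejected). Relative expression uses 2^−ΔΔCT with
technical replicates averaged into their biological replicate first:
ΔCT = CT(target) − CT(reference) per biological replicate, ΔΔCT relative
to the control-group mean ΔCT, rq = 2^−ΔΔCT. The control group's rq values
are centered at 1 in geometric mean by construction, and rq is invariant to
adding a constant to all CTs of a sample. Significance is a two-sided Welch
t-test on ΔCT values (not on rq — standard for ΔΔCT designs) at α = 0.05;
two identical constant groups give p = 1, two zero-variance groups with
different means give the smallest positive float. At 3 biological
replicates per group the simulated null rejection rate is ≈ 0.04; at 2
replicates per group Welch is conservative (≈ 0.02), so the calibration
simulation uses 3 per group while the qPCR generator's default design stays
at 2 biological × 3 technical replicates.

## Synthetic data: what it emulates and what it does not

* **Family proteomes.** Each subfamily has one ancestral sequence
  (420–560 aa) carrying the SNF2-like motif (60 aa) and Helicase-C-like
  motif (50 aa), each flanked by 40-aa family-wide conserved context, plus
  a 25-aa subfamily-private block, all at homologous positions; members are
  the ancestor mutated per position at 1 − conservation (default 0.9) with
  a 0–29 aa random tail. One-domain decoys carry a single bare motif copy
  in random sequence; background proteins are uniform-random. The flanking
  context encodes the biological fact that a family shares conservation
  beyond its generic domains — exactly what family-trained models exploit
  to out-discriminate Pfam-style domain models; with decoys carrying
  domain copies statistically identical to the family's *entire* planted
  signal, rc = 0.6 decoy exclusion would be impossible for any method.
* **CDS pairs.** Substitutions are planted at distinct nucleotide sites
  (Poisson-drawn counts around the Jukes–Cantor forward-mapped expected
  observed differences, sites weighted by their NG86 fractions, stop-
  creating changes never introduced), so NG86 recovers the target (Ka, Ks)
  in expectation; mean recovery over 200 × 500-codon replicates is within
  ±0.01 of (0.1, 0.3). No indels are simulated.
* **Genomes.** Chromosome gene grids with an 8-gene collinear block copied
  between chromosomes, a tandem pair, a proximal pair and a dispersed pair;
  duplicate CDSs are evolved at pair-specific rates recorded in the truth
  table; exon structure is random (1–4 exons).
* **qPCR.** CT values are Gaussian around means chosen so that
  E[ΔΔCT] = −log2(fold change), with a constitutive reference gene in
  every sample. The Gaussian CT error model is an assumption; replicate
  counts mirror a 2-biological × 3-technical design.

Passing tests on these data show the *algorithms* are correct and
calibrated under their own generative assumptions; they do not show that
real proteomes satisfy those assumptions (real families have indels,
heterogeneous rates, domain architecture variation, and non-uniform
background composition), and the literal counts of the original survey
(41/123/35 Arabidopsis domain proteins, 56 candidates, clade sizes
13/22/20) require the external Phytozome proteomes and are not reproduced
here.

## Problem sizes and determinism

Default test and acceptance runs use: 140-protein proteomes (2 × 10 family,
20 decoys, 100 background), 120-gene genomes, 100 bootstrap replicates,
200 Ka/Ks recovery replicates, 1000 null qPCR simulations, 100
oracle-equivalence draws — sizes at which every stochastic property above
is stable across seeds. All generators take explicit integer seeds
(numpy default_rng; no global state), stage outputs are byte-identical on
rerun, and the acceptance script derives all sub-seeds from its single
`--seed`.
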