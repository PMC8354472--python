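# Methods

`iesevo` reimplements, as a tested pipeline on synthetic data, the
comparative analysis of internal eliminated sequence (IES) evolution in
*Paramecium* germline (MIC) genomes: assembly-free genome sizing with
somatic-DNA (MAC) contamination correction, the IES catalog and its
reliability filters, projection of IES loci into gene-family alignments,
Bayesian ancestral reconstruction of presence/absence, per-branch
gain/loss rate estimation on the species tree, and discovery of mobile
(transposon-like) IES families.

## The gain/loss model

Each IES locus in a gene family evolves as a two-state continuous-time
Markov chain on the fixed, reconciled gene tree: gain rate g
(absent→present) and loss rate l (present→absent), shared by all loci of
the family. Priors are hierarchical exponentials, g, l ~ Exp(α) with
α ~ Exp(1). Tip observations are present/absent/uncertain; uncertain
tips enter as partial likelihood (1, 1). The root prior is the chain's
stationary distribution (l/(g+l), g/(g+l)) by default; `uniform` and
`fixed` are available (`root_prior`). Likelihoods use Felsenstein
pruning; per-node marginals use a two-pass (up–down) belief propagation.
Both are flattened to postorder edge arrays and JIT-compiled (numba)
because the MCMC evaluates them thousands of times per family. No
per-node rescaling is performed: with two states and trees of tens of
tips, partials stay far above the float64 underflow threshold (verified
against exhaustive enumeration to 1e-9 on 1,000 random trees of up to 8
tips).

Sampling is Metropolis-within-Gibbs: multiplicative (log-normal)
proposals for g and l with step sizes tuned toward 20–50% acceptance
during an initial tuning phase only (defaults: 5×10^5 iterations after
10^4 tuning iterations with tuning interval 10^3; the recovery studies
in the tests use 1,500/300/100 — see "Problem sizes" below); α is drawn
exactly from its Gamma(3, 1 + g + l) full conditional. Chains are
thinned (every 50th sample) after a 10% burn-in; effective sample size
and split-R̂ are reported per parameter (via arviz), and zero-variance
chains are flagged rather than silently accepted. Ancestral posteriors
are the pointwise mean of the per-sample marginals over retained
samples.

## Branch rates on the species tree

A species-tree branch i→j is represented in a gene family by every path
connecting a speciation node mapped to i with a speciation node mapped
to j through duplication nodes only (a duplication above j contributes
two paths, k = 2). Per path, p+ is the sum over edges of the positive
change in the probability of presence, p− the sum of negative changes —
per-edge increments rather than endpoint differences, so multiple
switches on a long path are counted; this choice is recorded in output
metadata. The rates are

    G_ij = Σ_g p+_gij / (Σ_g n_g·k_gij · b_ij)      (gains /kb /unit time)
    L_ij = Σ_g p−_gij / (Σ_g I_g·k_gij · b_ij)      (losses /IES /unit time)

with n_g the well-aligned alignment length (kb), I_g the family's locus
count, and b_ij the species branch length in substitutions/site, the
proxy for time. Paths interrupted by gene loss (no surviving speciation
endpoint) are excluded from k_gij. Insertion age is the species-tree
node to which the MRCA of all gene-tree nodes with posterior presence
above 0.99 maps: "New" (single species), "Node n" (internal), or "Old"
(predating the aurelia/caudatum split). Node numbering is the preorder
labeling of the fixture species tree, emitted in report headers.

Known estimator property: I_g counts all loci of the family, including
loci gained later or on other clades and hence never at risk on the
branch being scored. When recently gained loci are a substantial
fraction of the matrix, L_ij is biased downward by the at-risk fraction;
conversely, model misfit (a single reversible rate pair fitted to a
mixture of ancestral and recently gained loci genuinely maximizes at
inflated turnover) adds spurious decrements on deep branches. The
recovery study in `tests/test_acceptance.py` documents this honestly:
gain rates recover within 25% under the default study conditions, loss
rates do not, and the corresponding assertion is expected to fail. Rates
should be read as relative measures across branches, which is how the
downstream summaries use them.

## K-mer genome sizing and the contamination correction

Canonical 17-mers (lexicographic minimum of k-mer and reverse
complement) are counted array-wise (2-bit rolling encoding, chunked).
The error cutoff is the first local minimum after multiplicity 1; the
sequencing depth is the argmax of the histogram beyond it. The raw size
is the k-mer mass above the cutoff divided by the depth. Numerical
choice: the division uses a count-weighted mean multiplicity over the
single-copy band (cutoff to 1.5× the peak) rather than the integer
argmax — the true k-mer depth is non-integer (read-edge factor
(L−k+1)/L) and the counts at adjacent multiplicities are nearly tied
there, so the raw argmax alone carries an up-to-half-bin (several
percent) size error. The 1.5× bound keeps 2-copy (whole-genome
duplication) peaks out of the band.

MIC read sets contaminated by MAC DNA show two peaks: MIC-specific
k-mers at the MIC depth d, MAC-destined k-mers at D2 = d + contaminating
depth. The contamination fraction is estimated independently from the
IES retention score (IRS = retained/(retained+excised) reads) as
1 − mode of the IRS distribution (histogram mode, 0.05 bins centred on
multiples of 0.05; the mean is reported as a diagnostic; near-bimodal
distributions warn and take the larger-IRS mode). Under the generative
model this fraction equals (D2−d)/D2, which is exactly the share of
second-peak k-mer mass contributed by contaminating reads; the
correction therefore subtracts mac_fraction × (mass of the second-peak
band, delimited below by the inter-peak minimum and above by
`mac_attribution_max_depth`, default 500) and divides the remainder by
the refined MIC depth. K-mers deeper than the bound are high-copy
repeats attributed wholly to the MIC. With no resolvable second peak the
attribution falls back to the whole above-cutoff band. The correction is
exact on an ideal two-peak histogram and recovers a 1 Mb MIC truth
within 10% at 50% contamination in the simulation tests, where the
uncorrected estimate is off by ~100%.

## IES catalog semantics

The stored IES sequence is the excised fragment beginning with TA; the
MIC context is prefix + fragment + TA + suffix and excision leaves one
TA at the MAC junction. All internal coordinates are 0-based half-open;
GFF3 output is 1-based. Floating IESs (boundaries overlapping a tandem
motif) are detected by definition: every offset within ±10 bp whose
equally long TA-bounded fragment excises to the identical MAC sequence
is an alternative location; the window bounds the offset, not the span
of alternatives; the canonical representative is the leftmost offset.
Compartment (exon/intron/intergenic) is decided by the single retained-TA
base. Length classes: short < 35 bp, long > 100 bp; peak k of the
~10 bp-periodic length distribution covers [25+10(k−1), 34+10(k−1)] bp.
Weak IESs have IRS strictly greater than 0.10. Reliability filters drop
IESs on scaffolds under 10 kb and mark as uncertain the IESs in genes
with coverage below 15 reads or outside the 10th–90th coverage
percentiles (computed over mean per-gene depth per species); flagged
genes without an annotated IES are reported as potentially containing
IESs. MAC-variable regions extend inward from scaffold extremities in
2 kb windows until coverage reaches the expected depth, reported when at
least 4 kb.

## Comparative mapping

Gene families are single-linkage components of pairwise protein hits,
filtered to ≥3 members and ≥50% mean pairwise identity (identity =
matches / alignment length, gaps included). Conserved blocks replace an
external alignment masker with a deterministic three-parameter filter:
maximal runs of ≥10 columns with ≤20% gaps and ≥50% majority-residue
fraction; the mask is an explicit artifact so an external mask can be
substituted. An IES locus projects to the alignment columns of its
retained T and A plus any gap columns between them, one interval per
floating alternative; co-ortholog groups are connected components of the
shares-a-column relation (alternatives expanded before the test), and a
group containing a floating member with any alternative outside the
mask is discarded whole. Deeply conserved IESs are groups spanning ≥5 of
the 8 aurelia species with best cross-subclade identity ≥70% (mean also
reported).

## Mobile-IES discovery

External alignment and profile-search binaries are replaced by
in-package equivalents with *empirical* significance calibration,
because AT-rich sequences defeat theoretical score statistics: local
alignment scores (match 2, mismatch −3, gap open −5, extend −2; edlib
edit distance as a both-strand prefilter; per-sequence hit cap, harmless
under single-linkage clustering) are converted to expectation values by
an exponential tail fit to scores of dinucleotide-shuffled decoy pairs
of matched composition. Pairs pass the boundary rule when the alignment
spans the first and last 20 nt of both sequences; flank comparison
(100 nt each side, ≥75% identity over ≥150 nt) separates homologous-locus
pairs from candidate mobile pairs; candidates cluster single-linkage,
and families with ≥10 copies get a profile: center-star multiple
alignment, match columns = columns with ≤50% gaps (this trims ragged
family edges and the sparse insertion columns the merge creates, so the
profile length tracks the element length), per-column log-odds against
the empirical AT-rich IES background, consensus A+T > 92% flagged
composition-suspect rather than dropped. Scanning is a gapless both-
strand log-odds sweep with its own decoy calibration (E < 1e-3); a hit
is `mobile` when the match reaches both IES extremities within 3 bp,
`nested` otherwise. The per-species summary keeps families with ≥10
mobile copies in at least one species.

## The synthetic-data generator

The generator defines the study conditions and produces every input:

* **Species tree**: a fixed nine-species fixture — eight *P. aurelia*
  species in subclades A (six species) and B (*P. sonneborni*,
  *P. sexaurelia*) plus the *P. caudatum* outgroup — with branch lengths
  in substitutions/site (deep A/B split, outgroup branch 0.9).
* **Gene families**: birth–death expansions of the species tree
  (duplication and gene-loss rates per unit branch length); speciation
  nodes elided when one side dies, as reconciliation of extant genes
  would produce; families with <3 surviving genes are resimulated.
  Codon alignments evolve by substitutions only (stop codons rejected),
  so the protein alignment is gap-free unless gene loss intervenes.
* **IES histories**: gains arise as a Poisson process at gain_rate × kb
  per unit gene-tree branch length, each gain creating a new locus
  (infinite-sites: a lost locus is never regained); each existing locus
  is lost at loss_rate. Ancestral loci at the root are a free parameter
  (`root_density_per_kb`, default 2.0/kb, inside the observed per-kb
  density range of the sequenced genomes and giving the mix of ancestral
  and recently gained loci the real data show). Loci absent from every
  tip are recorded in the history but excluded from the presence matrix.
  Default tip masking (`uncertain_fraction`) is 0.
* **Genome pairs**: an AT-rich MAC backbone (72% A+T; IES interiors
  80%), genes tiled as CDS–intron–CDS blocks, IESs inserted at existing
  TA sites with a minimum spacing; lengths drawn from the 10-bp-periodic
  peak mixture (first peak < 35 bp dominant) plus a small >100 bp
  component. Floating IESs are engineered by writing an extra boundary
  motif copy into the MAC; mobile families get a consensus with 12-bp
  conserved terminal inverted repeats (the biology of nonautonomous DNA
  transposons, and what makes end-to-end homology detectable at ~70%
  identity) and substitution-only copy divergence solving
  (1−d)² + d²/3 = target identity; nested copies sit strictly inside
  longer IESs. Excising all IESs from the MIC yields the MAC bit-exactly
  by construction, and this round trip is tested on 1,000 random
  configurations.
* **Reads**: fixed-length error-prone substrings with a controlled
  fraction of read mass drawn from the MAC; the true per-IES
  retained/excised support counts are emitted for IRS work.

What the generator does not emulate: sequencing-quality ramps and indel
errors, assembly artifacts, satellite repeats, paralog-divergence rate
variation across sites, and selection on IES sequences. Passing tests
therefore demonstrate correctness of the estimators under the stated
generative model, not robustness to real-data artifacts; the filters
(coverage, scaffold size, conserved blocks) are exercised structurally
rather than against realistic failure modes.

## Problem sizes and numerical choices

Recovery studies run at sizes chosen to make sampling error small
relative to the tolerances they check: 500 families for branch-rate
recovery (≥50 expected events per graded branch) with 1,500-iteration
chains, 120 families for insertion dating, 1 Mb genomes at 30× for
sizing, and a 750-IES catalog (200 mobile + 50 nested + 500 unrelated)
for mobile discovery. Ties and degenerate inputs: g + l = 0 yields the
identity transition matrix; empty presence matrices are skipped with a
logged reason (mirroring families for which no starting probability
exists); the floating-offset representative is the leftmost; chi-squared
contrasts are computed without continuity correction and flagged when an
expected cell is below 5.
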