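# Methods

This note records the models panforge implements, the defaults it ships
with and why, the numerical choices that matter, and what the synthetic
benchmark does and does not establish about real data.

## Orthologous families

Pairwise protein hits arrive as 12-column m8 tables. Rows with E-value
above the cutoff (default 10⁻⁵) and self-hits are dropped. The similarity
graph weights each edge −log₁₀E, capped at 200 for E = 0 and averaged over
reciprocal directions; when only one direction was reported, that
direction's weight is used. Percent identity is deliberately not used as a
clustering filter — the E-value threshold is the only retention rule.

Markov clustering runs the standard recurrence on the column-stochastic
matrix: expand (matrix square), inflate (elementwise power, default 1.5,
renormalise), prune entries below 10⁻⁵, until the largest entry change
falls below 10⁻⁶ (at most 200 iterations, non-convergence is an error).
Self-loops are required for convergence; each node's loop defaults to its
maximum incident edge weight (floor 1.0). This choice matters: with unit
loops, a two-gene family joined by a strong edge (weight ≈ 50) converges to
the identity matrix — inflation concentrates flow on the diagonal — and the
pair splits. Max-incident loops keep connected pairs together, which is
also the convention of the reference MCL implementation. Clusters are read
off the limit matrix as connected components of its entries above 10⁻⁶
(smaller values are numerical residue). An optional `species_normalize`
toggle (off by default) divides each inter-genome edge by the mean weight
between its genome pair, damping genome-pair-wide similarity offsets; the
plain −log₁₀E weighting already reproduces the intended granularity on both
synthetic and constructed graphs, so the toggle is a knob, not a default.

Families are classified observationally: core = present in every genome,
specific = exactly one genome, accessory = everything between; genes absent
from the hit table become their own specific singletons, so the family set
always partitions the gene set. `single_copy` additionally requires exactly
one gene per genome.

## Pan-genome structure and openness

The presence/absence matrix has one row per family, one column per genome.
Accumulation curves average over random genome orderings (default 100
permutations): pan(n) counts families in at least one of the first n
genomes, core(n) those in all n. Averaging is a stabilisation choice —
single-ordering curves are monotone but noisy. Heaps' law is fit by least
squares on log pan(n) = log κ + γ log n; the openness verdict is γ > 0.05
rather than γ > 0, so sampling noise on a genuinely closed pan-genome does
not read as growth. A caveat worth knowing: γ measures curve growth, not
gene gain per se. A clade that gains nothing but loses heavily also shows a
rising pan curve (rarefaction), and with extreme loss rates the γ > 0.05
rule will call it open. The closed-world benchmark therefore uses zero gain
with mild loss, which is what "closed" means biologically: nearly all
strains share the same gene pool.

Annotation profiling (CAZyme classes, GO slims, COG letters) consumes
externally produced gene→label tables; a family carries a label if any
member does and is counted once per distinct label, separately per
partition, plus per-genome counts for specific families. Computing the
labels themselves (hmmscan, InterProScan, COG BLAST) is out of scope.

## Phylogenies

The sequence tree concatenates the single-copy core families into a
supermatrix (per-family column provenance retained), optionally filters
columns (gap fraction > 0.5 or most-common-residue share < 0.5), computes
p- or Poisson-corrected (−ln(1−p)) distances over shared ungapped columns,
and runs neighbor joining. NJ follows the Q-criterion with two
deterministic rules: exact ties go to the lexicographically smallest label
pair (a merged node inherits its smallest leaf label), and negative branch
lengths are clamped to zero. The final three nodes are joined by the
three-point formulas, giving an unrooted tree. NJ stands in for full
maximum-likelihood protein inference deliberately: the package's claims are
about topology recovery, which NJ guarantees on additive distances, not
about likelihood scores. Bootstrap supports resample alignment columns with
replacement, rebuild the tree, and annotate each internal edge with the
percentage of replicates containing the same bipartition.

The gene-content tree applies NJ (UPGMA available by flag, via average
linkage) to Manhattan distances between genome columns of the 0/1 matrix —
on binary data this equals the Hamming count of differing families.
Topological disagreement between the two trees is quantified by the
unrooted Robinson–Foulds distance (symmetric difference of non-trivial
bipartitions). Rooting and outgroup choice are left to the user; all
comparisons here are unrooted.

## Selection (dN/dS)

NG86 counting: each codon position's synonymous site fraction is the share
of its three alternative nucleotides that preserve the amino acid
(mutations to stop codons count as nonsynonymous), site totals are averaged
over the two sequences, observed differences are classified along all
mutational orders that avoid stops (equal weights; if every path crosses a
stop, all paths are counted), and proportions are corrected by the
Jukes–Cantor transform d = −(3/4)·ln(1 − (4/3)p), which errors at
saturation (p ≥ 3/4). Codon pairs containing stops or ambiguity are skipped
pairwise. When dS = 0, ω is reported as undefined — not 0 or ∞ — so
category summaries are not polluted by fake signals.

The M0 fit uses a GY94-style 61×61 rate matrix: single-nucleotide changes
at rate κ (transitions) or 1 (transversions), multiplied by ω when
nonsynonymous, uniform codon frequencies, scaled to one expected
substitution per codon per unit branch length. Uniform frequencies (rather
than F3×4) keep the estimator exactly consistent with the sequence
simulator, which uses the same matrix. The likelihood is computed by
pruning over site patterns (columns compressed to unique patterns), with
the transition matrices obtained from one symmetric eigendecomposition per
(ω, κ). ω, κ and all branch lengths are optimised jointly by L-BFGS-B on
log-transformed parameters, restarting from ω ∈ {0.1, 1.0, 2.0} and keeping
the best likelihood; an all-identical alignment short-circuits to zero
branch lengths and undefined ω. The fitted dN and dS are reported as the
tree length apportioned by the model's expected nonsynonymous/synonymous
flux. Site-heterogeneous models (beta-distributed ω classes and their
likelihood-ratio tests) are not implemented; ω here is a single genome-wide
average per family, which is the right tool for detecting purifying
regimes but cannot find positively selected sites.

Category summaries report, per annotation label, the family count, median
ω, interquartile range and purifying fraction (share with ω < 1); labels
with no usable family are omitted with a warning.

## Gene-family gain and loss

Family sizes evolve by the classic single-rate birth–death size-transition
model: with α = λt/(1+λt),
P(s→c) = Σⱼ C(s,j)·C(s+c−j−1, s−1)·α^(s+c−2j)·(1−2α)ʲ, size 0 absorbing.
The formula is valid for α < 0.5 (λt < 1); crossing that bound raises an
error, and the rate search is bounded accordingly. Transition matrices are
truncated at size_cap (default twice the largest observed size plus ten)
and rows renormalised, which bounds truncation error cheaply. Family
likelihoods come from pruning over size states with a uniform root prior on
1..size_cap — families are assumed to exist at the root, matching the
framing that the analysed families were inherited from the clade's common
ancestor. One global λ is fitted by bounded 1-D maximisation of the summed
log-likelihoods; a dataset where every family is invariant has no signal
and errors out.

Ancestral sizes are the joint max-probability assignment (max-product pass
with back-pointers); ties are broken toward the child state nearest the
parent (then the smaller state), which minimises the total absolute change
among equally likely assignments. Per-branch deltas give expansion
(delta > 0) and contraction (delta < 0) counts; terminal branches carry the
per-strain totals. Significance is Monte-Carlo: one shared null ensemble
(default 1000 families) re-evolves root sizes resampled from the
reconstructed roots under the fitted λ, and a family's p-value is the
fraction of null likelihoods at or below its own (with the +1 correction),
so p-values are approximately uniform when the data match the fitted model.
Per-branch rate variation and annotation-error corrections are out of
scope.

## Horizontal transfer detection

Hits are deduplicated by (query, subject), filtered by a percent-identity
floor (50 by default; a strict 90% screen is available as a flag, since
published pipelines use both and divide their roles ambiguously), E ≤ 10⁻⁵,
and the top 500 bit scores per gene. Each hit's bit score is normalised by
the gene's best self-group hit and summed within the self, close and distal
taxon groups; genes with no surviving self hit are excluded with a warning.

Cutoffs are read from the score distributions with a Gaussian KDE
(Silverman bandwidth). A usable valley must separate a minority
subpopulation — at most 60% of genes on the low side for close scores, at
most 25% on the high side for distal scores (recent transfers are a
minority class) — and must dip below half the density maxima on both
flanks, so wiggles inside one bulk are not read as bimodality. Mass-based
criteria are used because the distributions mix a point mass at zero (genes
with no hits in a group) with a continuous bulk, which defeats
mode-height heuristics. If the close distribution is unimodal the cutoff
falls back to its 25th percentile; if the distal distribution is unimodal
there is no transfer-like subpopulation and the cutoff is placed above the
observed maximum, so nothing is flagged. A gene is called transferred when
close_score < close_cutoff and distal_score ≥ distal_cutoff; its donor is
the taxon of its top-scoring distal hit. Screening against mobile-element
databases (plasmids, insertion sequences, phages) requires external
resources and is replaced by an annotation-table hook.

## Metal-reduction locus synteny

The reference locus is the seven-gene cluster
mtrD–mtrE–mtrF–omcA–mtrC–mtrA–mtrB with the feoA–feoB ferrous-iron operon
adjacent. Reference labels are mapped to families through the reference
genome's genes (errors on unclustered genes or two labels colliding in one
family). Per genome, copy numbers are counted genome-wide; gene order is
read along the contig carrying the longest run of cluster genes, where a
run tolerates up to 5 intervening non-cluster genes (figures of such loci
conventionally mark small insertions); a genome is complete when all seven
labels are present and occur within one contiguous run. Ties between
equally long runs resolve to the first contig in sorted order —
deterministic, and consistent with depicting a single locus. Profiles are
strand-aware in the reported order but orientation-invariant in copy
numbers and completeness.

## Synthetic data: what it emulates, and what it does not

The generator produces a pure-birth (Yule) ultrametric species tree
(pendant edges extended by the waiting time to the next speciation so all
branch lengths are positive), rescaled to a chosen root-to-tip height in
expected substitutions per codon. Gene content evolves along the tree:
core families are planted at the root and exempt from loss (the benchmark
needs a guaranteed planted core; the observational classifier remains free
to call never-lost accessory families core); root-accessory families are
exposed to loss; gains arrive per branch as Poisson(gain_rate·t), each
creating a new family; losses as Poisson(loss_rate·t), each deleting one
uniformly chosen non-core family. Transfers are implanted at the leaves,
Poisson(hgt_rate) per genome, as single-gene families with donors drawn
from a Vibrio-biased pool. Sequences evolve codon-wise under the same GY94
matrix as the estimator, one ω per family; the start codon is held fixed
and no indels are generated, so alignment is trivial by construction and
the (out-of-scope) multiple-alignment stage is unnecessary.

Hit tables are synthesised, not computed by an aligner: within-family pairs
get bit scores proportional to their actual protein identity with
Karlin–Altschul-shaped E-values, spurious cross-family hits are drawn at
marginal E-values just above 10⁻⁵ (the documented purpose of that cutoff is
to remove exactly such hits; drawing them in bit-score space would make
their significance depend on database size), and transfer-style profiles
give ordinary genes strong self/close hits and weak distal ones while
implanted genes hit their donor strongly and their close group below the
identity floor.

Defaults are one fixed set of study conditions: 24 genomes, 200 core + 300
root-accessory families, tree height 0.2, gain 150 and loss 400 per unit
branch length, 2 transfers per genome, ω = 0.2, κ = 2, 100 codons per
gene — chosen to give a genus-like variable fraction (~75% of families
variable) and an open pan-genome at desk scale. The closed-world benchmark
uses zero gain with mild loss (50), per the openness caveat above. Every
generator output is reproducible byte-for-byte from the config and seed.

Passing the synthetic benchmarks shows the estimators invert the generative
models they assume. Real data differ in ways the generator does not
emulate: indels and alignment error, rate heterogeneity across sites and
lineages, unequal codon frequencies, paralogy and partial-domain hits,
assembly fragmentation, and database taxon sampling biases in transfer
detection. Recovery rates reported here are therefore upper bounds on
real-data performance, not estimates of it.

## Problem sizes in the shipped benchmarks

The test suite and the acceptance script run the clustering recovery at the
full 24-genome scale (~700–800 families, ~12,000 genes); ω recovery uses
2000-codon alignments on 4 taxa with 20 replicates per ω ∈ {0.1, 0.5, 1.0};
rate recovery and p-value calibration use 300 families on an 8-leaf tree
with a 1000-family null; transfer detection uses ~500 genes with ~10%
implants; topology recovery uses 50 random 4–8-leaf trees. These sizes make
the whole suite run in about a minute on one CPU while keeping every
statistical check adequately powered.
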