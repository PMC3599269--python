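# Methods

This note documents the models and procedures implemented in `arborator`,
the parameter conventions and defaults, the design choices made where the
underlying methodology is genuinely open, and the limits of what the
synthetic-data closed loops demonstrate.

## Coordinates and formats

All in-memory coordinates are 0-based half-open; GFF3 on disk is 1-based
inclusive and converted at the IO boundary (`x_internal = x_gff − 1` for
starts, ends unchanged). FASTA is read and written through Biopython; the
GFF3 reader/writer covers the gene/mRNA/CDS/tRNA subset the pipeline
touches and is its own inverse on that dialect. Hit tables are TSV
(`query_id, chrom, start, end, strand, score`); ranks are recomputed on
read as 1..k per query by descending score, ties broken by (chromosome,
start) so rank assignment is independent of row order.

## Synthetic genome pairs

`simulate_ancestor` builds a gene-dense genome: ATG…stop ORFs of 40–120
codons with no internal stops, alternating strands, separated by intergenic
spacers (Poisson-length around the requested mean, minimum 20 bp) that
carry 1–2 planted homopolymer runs of length 3–12 (geometric). Random
sequence contributes many more natural runs ≥ 3 bp.

`evolve` derives a descendant: gene losses (per-gene probability), then
substitutions (sparing start/stop codons and never creating an in-frame
stop, so ortholog proteins stay alignable and the frameshift signal comes
only from planted indels), then inversions (≥2 whole genes,
intergenic-bounded), then reciprocal translocations (suffix swap at
intergenic breakpoints), then homopolymer ±1 bp indels. Indel probability
per run ≥ 3 bp is `hp_indel_rate`, multiplied by `a_bias` for A/T runs —
the A/T-skewed miscount spectrum characteristic of pyrosequencing. Every
event is recorded in a `TruthTable` (1-to-1 ortholog pairs, losses,
junction flank genes per rearrangement, final coordinates of every planted
indel).

Three generator constraints keep planted events *detectable by
construction*, mirroring the real events this models rather than tuning any
detector: translocation arms keep ≥ 2 genes (a single-gene arm is invisible
in gene-order space, and real translocated arms are chromosome-scale);
inversions keep ≥ 2 intact flanking genes between themselves and any other
breakpoint or chromosome end (a 1-gene fragment would fall below the
synteny-block threshold); and homopolymer indels are not planted within
6 bp of a gene boundary (a frame break in the terminal codons is
indistinguishable from an alignment end artifact). The default frameshift
regime (`hp_indel_rate ≈ 0.01`) puts one error in roughly 10–20% of genes —
the sparse, mostly-one-per-gene load seen in real unpolished pyrosequencing
assemblies — rather than saturating every gene with interacting indels.

The hit-table generator gives every retained gene a hit at its true locus
(score ≈ 100), adds with probability `decoy_prob` a *higher-scoring* decoy
at another gene's locus (score ≈ 105; the "best match is not the syntenic
ortholog" failure mode that motivates rescue), and a few low-scoring
spurious hits (score ≈ 40–60); queries whose ortholog was lost receive only
spurious hits.

What the generator does **not** emulate: paralogous gene families and
tandem duplications, introns, incremental assembly gaps inside genes,
alignment uncertainty beyond substitutions + ±1 indels, GC/replication
coverage biases, and read-level error processes. Passing closed loops
therefore demonstrate correctness of the *logic* under a clean noise model,
not performance on raw sequencing data.

## Ortholog assignment

Stage order and eligibility rules are fixed: triplet first pass (both
orientations accepted, conflicting claims void both), iterative in-window
rescue (anchors are the nearest assigned genes left and right on the same
query chromosome; candidates are the query's top-10 hit genes strictly
inside the open target-index window and unclaimed; exactly one candidate
assigns, zero or two or more skips; repeat to fixed point), then the
rank-1 fallback (free target, not overlapping a claimed prediction).

Two scheduling choices matter and were set by failure analysis on the
synthetic pairs (they affect which of several *eligible* rescues happens
first, never eligibility itself):

- **Within-round order:** tight windows first, then higher candidate hit
  score, then better rank, then gene id. Processing wide, weakly supported
  windows first let a lost gene's spurious hit claim a pending neighbour's
  true target and poison every window anchored on it.
- **Contested singletons defer to sequence evidence:** when two pending
  queries share the *same* single in-window candidate, at most one can be
  right and synteny cannot say which (this arises at inversion boundaries,
  where a window provably excludes the true target). Both are left to the
  fallback, whose rank-1 rule decides on sequence evidence alone.

After the fallback, the rescue loop is re-entered and the fallback
re-applied until the assignment set stops growing: fallback assignments at
chromosome ends and rearrangement junctions provide anchors that pure
synteny cannot, and stranded interior genes then rescue normally. The
fallback treats uncontested live rescue candidates as reserved and
processes queries by ascending rank-1 score (spurious hits claim last among
what remains).

Residual irrecoverable cases are structural: a chromosome-terminal or
junction-adjacent gene has no two same-chromosome anchors, so if its rank-1
hit is a decoy it can be neither rescued nor correctly assigned by a
rank-1-only fallback. On the standard benchmark pair (2 × 200 genes, 30%
decoys, 2% loss, one translocation, two inversions) this costs ≈ 1.5–2% of
retained genes; incorrect *syntenic* assignments are eliminated by the
contested-singleton rule.

The telomeric enrichment test is the one-sided hypergeometric tail
(drawing the observed number of flagged genes among the genes whose
midpoints fall in the first and last chromosome deciles). The tail of a
discrete statistic is conservative; the test suite checks calibration via
the randomized probability integral transform.

## ORF refinement and frameshifts

Boundary fixes scan in-frame codons outside the current prediction,
exclusive of the boundary codon, up to 9 codons (`stop_window_codons` /
`start_window_codons`). Stops: first in-frame stop extends the CDS to
include it. Starts: first upstream ATG with no intervening in-frame stop
extends; an intervening stop switches to a downstream scan that truncates
to the first ATG within the window. Intron-containing genes are left
untouched (a missing boundary may be a missing exon). Statuses partition
the input exactly (`corrected*`/`uncorrectable`/`unchanged`), and a fix
never changes strand or chromosome or moves a boundary by more than
27 bp + the stop codon.

Frameshift events are global-alignment gaps (edlib, mRNA-sense coding
sequences) of length ≢ 0 (mod 3); gaps touching either sequence's termini
are boundary artifacts and ignored. Homopolymer attribution takes the
maximal single-base run covering or abutting the gap in the target and, if
longer, in the query (a miscount changes the run length between species —
a deletion from a 3-run leaves a 2-run in the target, so the query run is
what certifies it); `min_homopolymer_run = 3`. Reported bases are on the
target's forward strand. The census counts a gene once regardless of its
event count; base and run-length histograms count every event.

## Polishing and assembly metrics

Variant integration requires support ≥ 0.6; calls are applied right-to-left
per chromosome so coordinates never shift under the applicator; overlapping
accepted calls resolve to the higher support (ties by position); a ref
mismatch rejects the call loudly. Each polishing round is a SNP phase
(call → filter → apply) followed by a fresh indel phase; rounds repeat
until nothing is applied, with an oscillation guard hashing the genome
state. With an exact truth-diff caller the fixed point is reached in one
applying round.

N50 is computed on the descending cumulative sum (largest L with contigs
≥ L covering half the filtered total; contigs < 500 bp excluded by
default); gaps are maximal `N` runs; coverage windows are non-overlapping
1 kb bins (a trailing bin under half a window merges into its neighbour) of
log2(window mean depth / genome-wide mean depth).

## Phylogenetic placement

The substitution model is equal-exchangeability (Poisson-type) with
stationary frequencies — uniform, or estimated from the alignment — for
amino acids, and the equal-rates (F81/JC) model for nucleotides. Its
transition matrix has the closed form
`P(t) = e^(−βt) I + (1 − e^(−βt)) 1πᵀ` with `β = 1/(1 − Σπ²)`, which makes
the likelihood along any single edge *linear* in `x = e^(−βt)`: per-edge
branch-length optimization is an exact bounded 1-D concave maximization
(derivative root by Brent), cycled over edges until the log-likelihood gain
drops below 1e-6, lengths clamped to [1e-8, 10]. Sweeps normally update all
edges against partials computed once per sweep (two tree passes); a sweep
that fails to improve the log-likelihood is redone with exact per-edge
recomputation, so optimization never regresses. The two edges meeting at a
rooted root are confounded on the unrooted tree and are canonicalized into
one. Likelihoods use Felsenstein pruning with per-pattern scaling and site
pattern compression; gaps and unknown residues are fully ambiguous; an
effective branch-length floor of 1e-9 keeps conflicting zero-length
configurations finite.

Candidate topologies are the five attachments of the focal species along
the backbone from the most basal ingroup lineage to the crown group,
rooted on the outgroup. Placement draws `sample_count` sets of
`genes_per_sample` families (without replacement within a set, only
families covering all seven taxa), concatenates, optimizes every candidate,
and takes the argmax (ties to the lowest topology id, flagged). Support is
RELL-style: alignment columns are resampled with replacement (multinomial
over compressed patterns) and candidate log-likelihoods re-evaluated at the
optimized branch lengths; support is the fraction of replicates won by the
sample's best topology. Branch lengths are reported per *site* (this model
has no codon structure), keyed by leaf-set split so rooted/unrooted edge
identities cannot be confused; `median_branch_lengths` gives per-split
medians across families, excluding and counting families whose
optimization fails.

## Growth phenotypes

A curve's baseline is the median of its first three ODs. Efficiency is the
maximum of the smoothed curve (moving average, window 3) minus baseline.
The maximum specific growth rate is the OLS slope of
`ln(od − baseline + floor)` over the log-linear band — the contiguous rise
between 5% and 80% of the total density gain — with `floor` defaulting to
the baseline itself, so the log argument is simply the OD and the slope of
an exponential segment is recovered exactly; `doubling = ln 2 / μ_max`. The
lag is where the band's fitted line crosses the baseline level
(tangent-intercept convention). A band-wide regression is used rather than
the single steepest sliding window because the steepest-window statistic is
an extreme-value estimator whose upward bias under measurement noise is
substantial at low OD; the band OLS recovers noiseless parameters exactly
and stays within a few percent at OD noise of 0.02. Curves with density
gain < 0.05 or non-positive slope are flagged non-growers.

Normalization: lag and doubling as log2(reference/isolate), efficiency as
log2(isolate/reference) — larger is better for all three; the reference
value per condition is the mean over same-plate reference replicates.
Group comparisons use the equal-variance two-sample t-test (Welch behind a
flag) with Bonferroni correction over the number of performed tests at
α = 0.2; conditions where both groups are identical constants are not
testable and are skipped.

The three-phase curve generator (flat baseline until the lag ends, then
exponential doubling of total OD, then a hard plateau at
baseline + efficiency) matches these extraction conventions by
construction. Real growth curves have smooth phase transitions, diauxic
shifts and instrument drift; closed-loop recovery here validates the
extraction conventions, not robustness to those effects.

## Configuration

`PipelineConfig` bundles the shared constants with their defaults: 9-codon
boundary windows, 0.6 variant support, homopolymer run threshold 3, top-10
rescue rank, 100 samples × 50 genes for placement, terminal decile fraction
0.1, 1 kb coverage windows, 500 bp contig floor, α = 0.2. Every stage also
accepts these as explicit keyword arguments.
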