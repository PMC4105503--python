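# Methods

This note records the models, conventions and design choices behind
`wgdscan`, in the spirit of a statistical-software methods appendix. It
states nothing the tests or `scripts/acceptance.py` do not themselves
compute.

## Coordinates, ranks and gene order

Annotations use GFF3 conventions externally (1-based, inclusive);
BED-like input has its 0-based starts converted on read. All synteny
logic runs on per-chromosome *ranks* — a contiguous 0..n−1 ordering by
ascending start with a deterministic (start, gene_id) tie-break — plus
start-to-start base-pair distances for the 100 kb rules. Strand is
carried but ignored: the block criteria are strand-agnostic. Genes on
unanchored scaffolds (chromosome names beginning `scaffold`, `contig`,
`un`, …) keep their records, count toward family size, and are excluded
from every synteny operation. When a gene id appears with several
transcripts, the longest CDS is its single representative.

## Family screening

A family member must carry at least one DBD domain hit *and* one HR-A/B
hit in the supplied domain table; NLS/NES/AHA hits are recorded but play
no role in inclusion. The table is treated as precomputed evidence —
profile/HMM searching and coiled-coil prediction are explicitly outside
this package. Redundant entries (different ids, same locus) are treated
as exact-locus duplicates and collapse through the one-representative
rule above.

## Homology

Two hit sources stand behind one interface. External BLAST outfmt-6
files are read directly (self-hits dropped, duplicate pairs keeping the
best e-value) and take precedence in the pipeline when supplied. The
built-in aligner — exact local alignment under BLOSUM62 with affine gaps
(open 11, extend 1; a k-long gap costs 11 + (k−1)) — serves fixture-scale
data: bitscore = (λS − ln K)/ln 2 with fixed constants λ = 0.267,
K = 0.041, and e-value = m·n·2^(−bitscore). This e-value model is
approximate; what matters downstream is that the 10⁻¹⁰/10⁻²⁰ thresholds
are honored on whichever source is active. `align_pair` reports exact
alignment identity; the bulk indexer computes score-only alignments plus
an edit-distance identity, and skips pairs sharing fewer than two exact
5-mers — a pure speed filter (unrelated random proteins essentially never
share two 5-mers, homologs above ~50% identity share many; the recovery
property is tested). Hits sort by (evalue, −bitscore, subject id), making
best-non-self-match queries total and order-independent.

Intraspecies scanning always queries a *within-genome* hit set. This is
not an optimization: with cross-species hits visible, a flank gene whose
recent duplicate died finds its ortholog in the other species (smaller
Ks, better e-value) instead of its ancient paralog, and ancient blocks
lose nearly all support.

## Block detection and grouping

For an anchor pair (a, b), each flank gene of a contributes support when
its best non-self match (E < 10⁻¹⁰) lies in b's ±15-gene window; matching
is one-way per the method's definition, with asymmetric support flagged
`non_reciprocal`. Matches are made one-to-one greedily in
ascending-e-value order so a single conserved gene cannot inflate
support. The anchor pair itself never counts. Support ≥ 4 ⇒ duplicated;
2–3 ⇒ flexible; else unsupported. Support for ancient pairs in a
twice-duplicated genome is structurally diluted — a flank's best match
points to its recent partner when that partner survives, and ties between
the two ancient-side copies split the rest — which is why ancient blocks
ride on far fewer conserved flanks than recent ones, and why the flexible
set matters for group connectivity.

Tandem clusters are maximal same-chromosome chains of family genes with
consecutive members within 100 kb and ≤ 10 non-family spacer genes;
`spacer_tier` reports the smallest of the tiers 0/≤1/≤5/≤10 covering the
chain. Tandem co-members are never used as anchor pairs, and each cluster
is collapsed to its first member before scanning: tandem copies share
their sibling's flanks, so scanning them separately would duplicate every
block of the cluster and inflate duplication-group membership.

Interspecies blocks collect one-to-one homolog pairs (E < 10⁻²⁰), each
gene within 100 kb of its anchor, requiring ≥ 3 pairs. Synteny quality is
2·matches/(|A|+|B|) over segments defined as the anchor's 15-gene window
intersected with the 100 kb region — the only segment extent the method
defines elsewhere. Orthologous groups are connected components over
(species, anchor) segments using interspecies blocks plus intraspecies
duplicated and (by default, configurably) flexible blocks as edges,
reported when they span ≥ 2 species.

## NG86 rates, windows, dating

Codon alignments are built by threading each CDS through a global
BLOSUM62 protein alignment (terminal stops stripped first); protein gaps
become `---` codons, and columns with a gap or ambiguity are excluded
from estimation. The NG86 conventions:

- Per-codon site counts: at each position, the synonymous fraction among
  the *viable* (non-stop) single-base changes; each codon therefore
  contributes exactly 3 sites, and counts are averaged over the two
  sequences.
- Differences: averaged with equal weight over all minimal substitution
  pathways avoiding stop codons; if every pathway crosses a stop the
  column is skipped entirely.
- Correction: Jukes–Cantor, d = −(3/4)·ln(1 − 4p/3), undefined
  (`saturated`) at p ≥ 3/4; ω = Ka/Ks, undefined when Ks = 0.

An independent brute-force oracle (its own codon table, explicit
permutation enumeration) checks these conventions to 10⁻¹⁰ over a
thousand random codon-pair batteries in the test suite.

Sliding windows span 150 nt stepped by 9 nt in *alignment* coordinates
(gap columns included in the span, gapped codons skipped inside), so the
window count floor((L−150)/9)+1 is a pure function of alignment length;
shorter alignments yield one flagged window.

Blocks are dated from the mean Ks of their conserved flanking pairs (the
anchor pair excluded; flexible blocks never dated), with sample standard
deviation, via T = Ks/(2λ)·10⁻⁶ Mya, λ = 6.1×10⁻⁹. When reproducing
printed per-block values the mean is rounded to 2 decimals before
conversion, which is the precision those values carry; pipeline mode uses
full precision. Two packaged barrel-medic rows are internally
inconsistent with the formula at 2-decimal precision (printed 63.05 and
65.66 vs computed 63.11 and 65.57); they are shipped as printed and
excluded from exact-reproduction checks. Event assignment: mean Ks < 0.25
⇒ recent; 0.45–1.0 ⇒ ancient; otherwise intermediate, the signature of a
segmental duplication between the two rounds.

## Loss bookkeeping

Within one species, duplication groups are connected components over
duplicated plus flexible pairs. Each group expects 2 post-ancient
lineages. A post-ancient lineage is visible today as a recent pair or a
single gene — except *segmental singles*: for an intermediate-Ks pair,
the member with no ancient-event edge is inferred to be a segmental
duplicate created between the rounds (ties: fewer ancient edges, then the
lexicographically later id), so it counts as an extra pre-recent lineage
but not as an ancient survivor. Then

- retained_post_ancient = recent_pairs + singles − segmental_singles,
- expected_post_recent = 2 × (retained_post_ancient + segmental_singles),
- losses are expectations minus observations; percentages round half
  away from zero.

Lineages with only the ancient WGD are scored from their
orthologous-group census (single/pair/absent per group):
expected = 2 × groups, retained = singles + 2 × pairs. A helper derives
the census from assembled `OrthologGroup`s; the packaged censuses cover
the two single-WGD lineages of the fixture data. One packaged census
leaves a one-gene discrepancy against the fixture family size (15
retained lineages vs 16 genes in groups, plausibly a tandem duplicate);
the census figures are taken as authoritative for loss counting.

## The simulator

`synthetic_data` emulates a papilionoid-like history: an ancestral gene
order; a shared ancient WGD whose pairs measure Ks ≈ 0.70 today; an
optional lineage-specific recent WGD at Ks ≈ 0.155; per-copy loss after
each round; occasional adjacent tandem duplication; codon sequences
(uniform over sense codons) diverged under purifying selection. Defaults
are the study conditions: family per-copy loss 0.25 (ancient) and 0.16
(recent); background genes fractionate harder, 0.40/0.45 — without that
contrast, nearly every flank keeps its recent partner and ancient blocks
fall below the 2-pair support floor, which is also why real ancient
blocks carry few conserved flanks. ω defaults to 0.3 and gene length to
300 codons (long enough to measure Ks ≈ 0.7 well short of saturation);
intergenic spacing defaults to 2 kb (gene-dense, ~33 genes/100 kb) and
the multi-lineage study configs use 6 kb (~14 genes/100 kb).

Divergence is applied time-layered and symmetrically: between consecutive
events every surviving gene evolves by half the Ks depth separating them,
so *every* pair coalescing at an event measures that event's depth — the
behaviour a rate-constant clock implies, and the reason cross pairs from
two stacked WGDs measure ≈ 0.70 rather than 0.70 + 2×0.155. Fractionation
after a shared WGD is lineage-specific: loss draws are deferred until
after the split. `evolve_pair` proposes uniform single-base changes,
accepts synonymous ones at rate 1 and nonsynonymous at rate ω, rejects
stop-creating changes, and stops when the NG86-measured Ks along the
branch first crosses its target (incremental per-codon bookkeeping makes
this cheap); realized Ks therefore overshoots targets by at most about
one substitution's worth.

Truth tables record the full genealogy: every surviving homolog pair with
its generating event and realized Ks, tandem clusters, and per-locus
survivors, from which true duplication groups, ortholog censuses and loss
reports are derived for comparison with pipeline output.

What the simulator does *not* model — codon-usage bias, indels within
CDS, transposons, rearrangements beyond whole-chromosome duplication,
gene-length variation — means passing tests demonstrate the algorithms'
correctness under clean conditions, not robustness to annotation noise or
structural variation in real genomes.

## Problem sizes and geometry of the test configurations

Three study configurations are used (sizes chosen as the package's own
desk-scale analogs):

- *Sensitivity*: one WGD at Ks 0.15, zero loss, 4 family loci on 2×80
  gene chromosomes — every true homoeolog pair must be recovered as
  duplicated with no extra block.
- *Shuffle control*: gene order randomized at a 40,000-gene scale with a
  truth-derived hit index. The scale is essential: a shuffled homolog
  lands in a given 30-gene window with probability ≈ window/genome, so
  at fixture scale (hundreds of genes) the expected number of chance
  matches per anchor pair is far above the support floor and the
  zero-block claim would be false; at genome scale it holds with large
  margin. The truth index isolates position logic; sequence-level
  homology is tested separately.
- *Two-lineage analog*: 17 family loci, shared ancient + one-lineage
  recent WGD, one locus per chromosome (17×110 ancestral genes). Two
  geometric constraints drive this layout: fractionation compresses
  ranks roughly threefold in the twice-duplicated lineage, so loci
  closer than ~3 window-widths ancestrally would end up inside each
  other's ±15-gene windows and merge spuriously; and differential
  compression between lineages shrinks the shared ancestral span of two
  100 kb windows, which the 6 kb intergenic spacing keeps comfortably
  above the 3-pair floor. One locus per chromosome removes the first
  failure mode structurally, as in real genomes where family members
  mostly occupy separate chromosomes. On this configuration the
  pipeline's loss reports equal the bookkeeping applied to the true
  history, for both the two-round and one-round lineage, and the flank-Ks
  histogram is cleanly bimodal with an empty valley between the peaks.

## Known limitations

- The built-in e-value model is not BLAST's; absolute e-values differ
  from database-search values even though threshold behaviour is
  consistent within a run.
- One-way best-match support (with the reciprocity flag) follows the
  method's definition; a reciprocal-best-hit variant would be stricter
  and is not implemented.
- Whole-chromosome duplication with independent per-gene loss is an
  idealization of fractionation; no segmental or partial-chromosome
  duplication is simulated (segmental events enter only through the
  intermediate-Ks classification of real data).
- Dating inherits the rate-constancy assumption of the molecular clock;
  lineages with elevated synonymous rates will date the same event older,
  as the packaged fixture's barrel-medic rows illustrate.
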