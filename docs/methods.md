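# Methods

polyprof reconstructs the nuclear ancestry ("genome composition") of
mixed-ploidy plant individuals from short-read data, and tests whether a
conflicting organelle phylogeny can be explained by incomplete lineage
sorting (ILS). This note documents the models, the algorithms, the defaults
and the choices made where the design was genuinely open.

## The problem

In a species complex with diploids and allopolyploids, the diploids can be
phased — each single-copy locus yields two haplotype sequences — but the
polyploids cannot: a hexaploid carries six alleles per locus in unknown
combinations, possibly inherited from several divergent diploid lineages
(subgenomes). The strategy is therefore asymmetric: build a clade-labelled
reference panel of phased diploid alleles, then interrogate the polyploid one
read pair at a time, asking which nuclear clade each pair is phylogenetically
nested within. The per-clade proportions of placed reads estimate the
subgenome composition. Cytonuclear discordance (organelle tree conflicting
with the nuclear tree) is tested separately by coalescent simulation.

## Multispecies coalescent simulation (`msc_sim`)

Gene trees are simulated under the standard multispecies coalescent: within a
species-tree branch carrying k lineages, the waiting time to the next
coalescence is Exponential with rate k(k−1)/2, in that branch's coalescent
units (time / 2N generations); pairs merge uniformly at random; surviving
lineages pass to the parent branch; the root branch is treated as infinite so
every replicate coalesces fully. Correctness is pinned to the closed form for
three taxa — P(concordant) = 1 − (2/3)e^(−t) — and cross-checked in the test
suite against msprime configured so one generation equals one coalescent
unit.

For the ILS test the species tree is prepared as follows:
terminal branches are set to an arbitrary length of 1 (terminal branch
lengths of a multigene coalescent species tree are not estimable), tips are
extended to make the tree ultrametric, and all branch lengths are doubled to
reflect the twofold smaller effective population size of uniparentally
inherited organelle genomes in a monoecious species. 100 000 gene trees are
simulated and censused: a tree counts as "clade-monophyletic" when every
ingroup clade's samples form a rooted monophyletic group, and it matches the
organelle topology when clade III is sister to clades I+II+IV (the
relationships within I+II+IV are unconstrained by default; a strict mode
compares the full rooted shape — supply a fully resolved target to
`census_topologies` to get it). The external tools' mutation-rate and
population-size settings only rescale coalescent units when just topology
frequencies are consumed, so the grid of such settings is represented by a
single global branch-length scale factor (default grid 0.5, 1, 2), with the
coefficient of variation of the match fraction reported across the grid.

One sample per species is simulated by default (the census then reduces to
the species-tree topology census); per-species sample counts are
configurable, and the generator uses the full per-clade allele counts.
Reproducibility: tree i of a stream is drawn from a counter-derived RNG
stream `default_rng((seed, i))`, so streams are identical regardless of
chunking and can be generated in parallel.

A point worth flagging: for a star species tree the coalescent is uniform
over *labeled histories*, not topologies — balanced four-tip shapes appear at
1/9 and caterpillars at 1/18, which the test suite asserts.

## Phasing (`phasing`)

Input is an exon-scale pileup of ungapped mapped reads (a minimal SAM subset
or the generator's aligned-read table). Heterozygous-site calling removes
bases below Q20, requires the two candidate alleles to reach the depth-policy
support thresholds — at least 3 reads per position and 2 per variant for
resequencing data, 10 and 3 for high-coverage (≥20×) data — and then applies
a quality-aware likelihood-ratio genotype test: the site is called only if a
balanced heterozygote explains the two allele counts better than a homozygote
whose minor bases are sequencing errors at the observed quality. The LRT
matters in practice: at 1% error and 20× depth, coincident errors produce
candidate sites with ~18:2 support that pass the count thresholds yet are
almost certainly homozygous, and such sites otherwise corrupt phasing.

Phasing is a greedy position-ordered haplotype assembly. Mates are linked
through their pair id so a fragment is one unit of evidence. Sites are phased
left to right; each new site's orientation is decided by majority vote over
fragments linking it to already-phased sites; a site with no linking fragment
starts a new phase block. Only the largest block is retained and the het
sites of other blocks are masked (N) — exons are selected to be longer than
the read-pair insert, so in practice nearly everything is one block. Sites
whose orientation votes are close to a coin flip (< 80% consistent) are
treated as spurious and contribute no phase evidence. Fragments are assigned
to the haplotype they mismatch least; equal mismatch counts (chimeras)
conflict with both haplotypes and are discarded with a reason code. One
refinement pass re-derives each haplotype's allele per site as the
per-haplotype majority and reassigns fragments on the sites where the
haplotypes still differ. Haplotype sequences are per-haplotype majority bases
at every position (fragments covering no informative site count toward both),
masked N wherever the haplotype's depth falls below the policy threshold;
phased sequences with fewer than 200 usable bases are discarded.

This assembler takes the place of general-purpose read-backed phasing tools;
switch
errors are negligible at exon scale because fragments span multiple het
sites, which the fixtures respect — het sites farther apart than one pair
span (550 bp) are physically unlinkable by read backing and are masked, by
design.

The organelle majority-consensus caller is separate: per position, the
majority base where depth strictly exceeds a floor (set by the caller to five
times the expected nuclear depth, which discards organelle-to-nucleus
transfers whose coverage tracks the nuclear genome), N otherwise, ties
resolving to the reference base and logged.

## Reference panel (`allele_reference`)

Candidate loci are the genes whose longest exon strictly exceeds the mean
insert size (550 bp); the longest exon of each is used. Per gene, the panel
alignment holds the phased diploid alleles, the two F1-hybrid alleles and one
sequence per congener. Screening requires (i) both congeners present,
(ii) at least 4 sequences in each of the four nuclear clades, (iii) at least
30 sequences in total — all inclusive thresholds, counting every sequence
including congeners. Trees are inferred by neighbor joining on Jukes–Cantor
distances computed over shared ungapped non-N sites (pairs with no shared
sites get the maximum observed distance and a warning; mismatch fractions are
clipped below the JC saturation bound). NJ input rows are sorted by label and
minimum-Q ties break in row-major order, so inference is exactly
deterministic — the reason a distance method was preferred over maximum
likelihood: downstream logic consumes only the clade membership of nested
leaves, and the tests verify NJ against exhaustive least-squares topology
search and Bio.Phylo's NJ. An `engine` slot allows a likelihood method to be
swapped in. Trees are rooted on the first congener only; the second stays in
the alignment as a screening control. Bootstrap support is not computed
(nothing downstream uses it).

The F1 hybrid — one parent from clade I, one from clade IV — is the built-in
informativeness control: a gene is retained only if one F1 allele is nested
within clade I and the other within clade IV ("nested" = its sister group
consists exclusively of leaves of that clade). Genes failing this are either
too invariant to place reads or potentially paralogous.

## Read placement (`placement`)

A pair is eligible for a gene when both mates are fully contained in the
exon interval (a fragment-containment mode is also provided; for end-pair
mates the two coincide). The two mates are merged into a single row aligned
to the panel: each mate, in its better-scoring orientation, is locally
aligned (match +1, mismatch −1, gap open −4, extend −1) to the panel
consensus; aligned bases are written into a row of panel width; read bases
inserted relative to the panel are dropped and counted, so panel columns are
never altered — this keeps trimming coordinates and the F1 sanity check
stable, a deliberate divergence from profile-alignment tools that may open
new columns. A mate scoring below 40% of its length contributes nothing; if
neither mate aligns, the pair is unplaced (random sequence reliably fails
this floor).

The alignment is trimmed to the merged read's span; spans over 500 columns
are cut equally from both ends (a 500-column cap fixes the tree-inference
problem size; trimming symmetrically keeps the read centred); merged reads
with fewer than 250 remaining
bases are discarded as too short. The sequence-length discard is applied to
the merged read; panel sequences are kept regardless of their content in the
window (the screening criteria already guaranteed panel adequacy). A tree is
re-inferred on the trimmed alignment with the same NJ engine and rooted on
the congener. Two checks then gate assignment. First, both F1 alleles must
still be nested in clades I and IV respectively, the read leaf being ignored
while checking — otherwise the window has lost diagnostic signal and the pair
is discarded (`discarded_f1_check`). Once verified, each F1 allele counts as
a member of its verified parental clade for the read's sister-group test:
the F1's clade-IV allele *is* a clade-IV haplotype, and treating it as
foreign would systematically discard clade-IV reads (clades II/III contain no
F1 allele), biasing every composition. Second, the read's own sister group
must consist of leaves of exactly one nuclear clade — that clade is the
assignment; a read sister to a whole clade's stem counts as nested in it.
Outgroup-only sister groups are unplaced; mixed groups are discarded
(`discarded_mixed_sister`). Pairs are placed independently, so no read
influences another's assignment.

Per individual, assigned counts and proportions over the four clades plus a
discard-reason tally form the composition profile. For diploids and the F1
hybrid, placement runs in leave-one-out mode: the focal individual's alleles
are removed from every gene alignment, genes failing re-screening are skipped
for that individual (re-screening is applied deliberately; assigning against
a depleted clade would be misleading), and the known ancestry provides the
calibration: pure diploids should assign almost entirely to their own clade
and the F1 should split evenly between clades I and IV.

## Synthetic data (`synthetic_data`)

The generator emulates the study design so every stage is testable without
any download. Defaults, chosen once to mirror the study conditions:

- Species tree: `(outgroup2:10,(outgroup1:8,(I:6,(II:5,(III:4,IV:4):1):1):2):2)`
  — four ingroup clades with clade II sister to (III,IV), two successively
  deeper congener outgroups; coalescent units. Long terminal branches make
  clades almost always monophyletic per gene while gene trees stay
  heterogeneous across loci.
- 50 genes, exon lengths uniform on 600–900 bp (all longer than the 550 bp
  insert, as candidate loci are by construction); per-gene flanking sequence
  of one insert length on both sides so fragment overhang behaves like real
  mapping.
- 16 diploids (4 per clade, each contributing two alleles per gene), one F1
  hybrid (one clade-I and one clade-IV allele per gene), one hexaploid
  (subgenomes 2:2:2 over clades II/III/IV) and one dodecaploid (4:4:4),
  matching the admixture scenarios the analysis is meant to resolve.
  Polyploid subgenome alleles are drawn without replacement from distinct
  coalescent lineages within each clade, so polyploids are allopolyploid-like.
- Substitution model: a symmetric two-parameter (transition-biased) model,
  κ = 2, at 0.01 substitutions per site per coalescent unit. Downstream
  consumers use only topology and nesting, so a richer model would add
  nothing; the rate yields clade-diagnostic sites in ≥90% of genes, and
  per-gene diagnostic positions are recorded in the truth tables.
- Reads: 250 bp pairs, insert 550 bp (50 bp unsequenced middle), per-base
  errors iid at `error_rate`, quality strings encoding that rate (constant
  Q40 when error-free, Q20 at 1%). `depth` is mean coverage per haploid
  genome copy — the convention of read simulators given one reference per
  haplotype — so a hexaploid at depth 20 is sequenced at 120× total; a
  polyploid at 20× total (~3× per copy) is not a regime any per-read
  placement method is designed for. Fragment starts are uniform across the
  exon including flank overhang, so mapped coverage is uniform along the exon
  and only a subset of pairs is fully contained (as with real containment
  filters); a `tile` mode lays fragments on an even grid per haplotype for
  coverage-controlled phasing experiments.
- Determinism: every stage derives its RNG stream from (seed, stage, gene,
  individual) counters; identical seeds give byte-identical outputs.

What the generator does **not** emulate: indels and structural variation
(reads are ungapped relative to their exon — the placement profile-aligner is
still exercised, but not with real gap structure), realistic quality-score
profiles (qualities are uniform, so quality masking is exercised only at the
threshold), paralogy (the F1 filter's main real-world target), and
between-individual depth variation. Passing tests therefore demonstrate the
pipeline's logic and its statistical behaviour under the assumed model, not
robustness to mapping artefacts or reference bias in real data.

## Sample-metadata rules (`io_core`)

Photosynthetic type: individuals with carbon isotope ratio strictly below
−17‰ are non-C4, the boundary value classifying as C4; the further
separation of non-C4 into C3 vs C3+C4 requires anatomy or expression data
and is out of scope. Ploidy from 2C genome size: a size matches ploidy p when
it falls in the measured diploid range (1.78–2.77 pg/2C) scaled by p/2,
candidates up to 12x; with no strict match the ranges are widened ±25%
(multiplicatively at the endpoints), and failing that the nearest scaled
midpoint wins. Scaled ranges overlap intrinsically above hexaploid
(2.77(p−2) ≥ 1.78p for p ≥ 5.6), so multiple matches are possible; ties
resolve to the largest matching level and are flagged "ambiguous". Only a
unique diploid-range match is "confident" — polyploid calls are flagged
"possible", reflecting that the underlying diploid range is the only
karyotype-backed calibration. Occupancy trimming counts both '-' and 'N' as
non-coverage (both arise from the consensus/phasing mask), and occupancy
thresholds count sequences, not individuals (an individual may contribute two
alleles; counting sequences is the convention adopted here).

## Problem sizes and runtime

The default study scale — 50 genes, 21 individuals, depth 20 per copy,
~13 000 placed pairs, 100 000 coalescent replicates per census — was chosen
so the entire analysis reruns from scratch in minutes on one core while
keeping Monte-Carlo error well inside the tolerances used by the tests
(binomial SE < 0.012 on every composition proportion). All thresholds quoted
above (Q20; depth policies (3,2)/(10,3); 200 bp phased length; 500 bp cap;
250 bp minimum; screening 4-per-clade and 30-total; insert 550 bp; −17‰;
1.78–2.77 pg) are the pipeline's operating constants, exposed as parameters
with these defaults.

## Known limitations

- NJ on JC distances can misplace a read when the trimmed window carries
  almost no signal; the mixed-sister and F1 checks catch most such cases, but
  a tie can still resolve to a clean sister group and be assigned.
- The placement profile-aligner drops read insertions relative to the panel,
  so indel-rich loci would lose signal.
- Leave-one-out re-screening can skip genes for individuals whose clade is
  minimally represented, shrinking calibration sample sizes.
- The ILS census depends on the species tree's internal branch lengths; when
  they are not known from data (as for the synthetic default), the reported
  match fraction characterizes the simulated conditions, not any empirical
  system.
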