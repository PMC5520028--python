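# Methods

This note documents the models and decision rules the package implements,
the defaults and why they are what they are, what the synthetic-data
generator does and does not emulate, and the numerical conventions that
make runs reproducible.

## Multiheme cytochromes and iron-reduction prediction

c-type cytochromes bind heme covalently at the CXXCH pattern: cysteine,
two arbitrary residues, cysteine, histidine. Proteins that tile many of
these motifs — multiheme cytochromes (MHCs) — are a hallmark of
dissimilatory metal reducers such as *Geobacter* and *Shewanella*, so an
MHC census is a usable proxy for iron-reduction capacity.

Decision rules: a protein is an MHC at **≥10 motifs**; a genome is a
predicted iron reducer at **≥4 MHCs**. Both thresholds are configurable
(`Thresholds.mhc_min_motifs`, `iron_min_mhcs`).

Counting conventions, chosen where the definition is genuinely open:

* **Overlapping windows all count.** Heme-binding sites tile densely in
  real cytochromes and overlap counting is the deterministic reading; an
  alternative non-overlapping greedy count would depend on scan direction.
  This choice is documented rather than hidden because either reading is
  defensible.
* **`X` fails the match at every motif position**, including the two
  unconstrained middle positions; ambiguous residues can therefore only
  undercount, never inflate. `U` (selenocysteine) is a legal residue but
  matches nothing in the motif.
* Sequences are uppercased at ingest and a single terminal stop `*` is
  stripped; an internal `*` is tolerated but blocks any window containing
  it.

`evaluate_predictor` reproduces the validation arithmetic used for
reference-proteome surveys: prevalence is flagged genomes over all
genomes; precision is, among flagged genomes with a known label, the
fraction labelled as true iron reducers. Flagged genomes without a label
are excluded from precision with a warning; with no labelled flagged
genome, precision is reported as missing rather than zero. A 2015-era
reference snapshot cannot be reconstructed, so the predictor is validated
on synthetic labels only.

## Hydrogenase typing and Group A resolution

Catalytic subunits are typed from profile hits (labels `NiFe_G1..G4`,
`FeFe_GA/GB/GC`, `Fe_hmd`); the best bit score wins, exact ties break
lexicographically and are flagged ambiguous. Phylogenetic placement
against curated reference alignments is out of scope; group identity is
taken from the profile labels.

[FeFe] Group A subgroups are functionally opposite — A1 enzymes are
monomeric and H₂-evolving, A3 enzymes electron-bifurcate between H₂,
ferredoxin and NAD — but sequence-indistinguishable, so they are separated
by operon context: A3 requires the two accessory subunits *hydB* (a
diaphorase ortholog with multiple [4Fe-4S] clusters) and *hydC* (a small
[2Fe-2S] protein) encoded downstream of the catalytic gene.

The implemented rule examines up to `operon_window` genes (default **3**)
downstream of the catalytic gene in its reading direction (increasing
ordinal on `+`, decreasing on `−`; ordinals are strand-agnostic positions
by ascending start coordinate):

* both a *hydB*-hit gene and a *hydC*-hit gene, **on the catalytic gene's
  strand**, inside the window → **A3**;
* window truncated by the scaffold end with A3 evidence incomplete →
  **A_unresolved** (this covers both no-evidence and one-of-two edge
  cases);
* otherwise → **A1**.

A window of 3 covers hydABC(D) arrangements while limiting false joins
across operon boundaries; the co-orientation requirement encodes the
biology of co-transcribed operons. Both are design choices where the
method description is silent, and both are configurable. An optional
sequence-signature fallback (≥2 CXXCXXC-type clusters for hydB; <120
residues with a CXXGXC-type signature for hydC) exists for hit-free
fixtures and is off by default.

Genome-level co-occurrence fractions (`cooccurrence_stats`) are simple
conditional frequencies — |genomes with both| / |genomes with the first| —
reported as missing when the denominator is empty. Rnf-complex presence is
any `rnf*` marker hit in the genome.

## Pathway profiling

A rule is a conjunction of clauses; a clause is a disjunction of
interchangeable marker genes. Status: **complete** when every clause is
satisfied, **absent** when no clause is, **partial** otherwise. A clause
may be negated (satisfied when none of its genes is present); partial
nitrification — hydroxylamine dehydrogenase present *and* ammonia
monooxygenase absent — needs this. With negation the poles are anchored on
positive clauses: a genome satisfying no positive clause is **absent**
even though it vacuously satisfies every negated clause, so an empty
genome can never be "partial". Rules with only negated clauses are
rejected at load. The monotonicity guarantee (adding genes only moves a
status toward complete) holds for negation-free rules and is asserted for
those.

Fermentation and complex-carbon degradation are not all-or-nothing and are
profiled as gene counts bucketed into none/low/high tiers; the low/high
split is the upper tercile of the non-zero counts across genomes in the
matrix. The rulebook is data (`data/pathway_rules.tsv`), not code: it is a
reconstruction of the pathway claims the package reports on
(denitrification to N₂, DNRA, N₂ fixation, partial nitrification,
anammox, sulfate reduction and sulfur oxidation, Wood–Ljungdahl, Calvin
RuBisCO forms, hydrogenotrophic methanogenesis, Rnf, formate
dehydrogenase), and users can swap in their own marker lists without code
change.

The profile matrix keeps genomes whose mean relative abundance across
samples exceeds `rare_abundance_frac` (default **0.001**, the 0.1% row
filter), ordered by descending abundance.

## Bin quality, dereplication, community accounting

**Completeness** = 100 × |markers hit by ≥1 gene| / |marker set|;
**contamination** = 100 × |markers hit by ≥2 distinct genes| / |marker
set|, against a 51-gene single-copy set (ribosomal proteins plus infC and
pheS by default). High quality is strict: completeness **>70** and
contamination **<10**. Published pipelines differ in the exact estimator
(some weight by lineage or collocate markers); this package uses the plain
counting form and states it.

**Pairwise identity** between two bins is estimated scaffold-by-scaffold:
candidate scaffold pairs must share a 21-mer (random unrelated sequences
essentially never do), are aligned globally (edlib, edit distance capped
at 30% of the longer length), and contribute identity 1 − d/max(len)
weighted by matched length; the aligned fraction is matched length over
the shorter genome. This is a self-contained estimator adequate for
fixture-scale genomes, not a whole-genome aligner. **Dereplication** is
single-linkage clustering over edges with identity ≥ **0.98** and aligned
fraction ≥ **0.5** — 98% is the community-standard strain boundary; the
method description prints no threshold, so both are configurable. Each
cluster's representative is its most complete bin (ties: lower
contamination, then bin id).

**rpS3 accounting**: one rpS3 per organism is the biological expectation;
sequences are clustered greedily (longest first, ties by id) at **99%**
global amino-acid identity, each cluster represented by its founding
centroid. Relative abundance of an organism is its rpS3-scaffold depth
over the total across cluster representatives, per sample, averaged.
Genome (bin) abundance is the length-weighted mean scaffold depth —
equivalent to total mapped bases per genome — normalized per sample, so
scaling a sample's depths is invisible. The rank-abundance summary
reports, among the top-k (default 50) organisms, how many are binned, and
among unbinned organisms the fraction below the rarity line.

An exploratory `abundance_correlation` utility computes Spearman
correlations restricted to genome pairs whose mean abundances are within
`cooccur_ratio` (default 10:1) fold of each other; the ratio-thresholded
screen it mirrors is ambiguous in the literature and this is documented as
one interpretation.

**Alignment preparation** for ribosomal-protein trees runs exactly three
passes, never iterated: (1) within each per-gene block, delete columns
with gap fraction > **0.90** computed over the full taxon set (taxa absent
from a block count as all-gap); (2) concatenate; (3) drop taxa with
non-gap fraction < **0.50**. Taxa with ≥ **450** non-gap positions are
tree-eligible. Because pass-1 gap fractions are computed before taxa are
dropped, re-trimming an output in which taxa *were* dropped can remove
further columns; the idempotency guarantee therefore applies to the same
taxon set, and the tests assert it on fixtures without taxon drops. Tree
inference itself is out of scope.

**Taxonomy consensus** over up to three evidence lines (16S, concatenated
ribosomal proteins, per-gene vote) is the longest shared rank prefix —
the most specific level at which all present lines agree — with
`unassigned` for an empty prefix. Missing lines are skipped with a
warning; the rule is order-invariant and idempotent.

## Synthetic data: what it emulates and what it does not

The generator emits every format the pipeline reads (protein FASTA,
nucleotide FASTA, GFF3, domtblout-dialect hit table, coverage and
membership TSVs) as a pure function of its arguments and seed, with a
truth JSON alongside.

* **Guarded motif planting.** Background residues and motif middles are
  drawn from the 18 amino acids excluding C and H, so a CXXCH window can
  only exist where one was planted: a window needs C at offsets 0 and 3
  and H at offset 4, and those letters occur only inside payloads. Planted
  counts are therefore exact, which is what makes the motif-recovery tests
  equalities rather than tolerances. A realistic full-alphabet mode exists
  for oracle-versus-implementation testing; there the recorded truth is an
  independent brute-force scan.
* **Operon layouts** enumerate catalytic gene, strand, co- and
  counter-oriented neighbors and scaffold-end truncation; the planted
  label is computed by an independent statement of the A1/A3 rule. In the
  community generator all operons sit on the `+` strand mid-scaffold,
  padded with hit-free genes so neighboring operons cannot leak evidence
  into each other's windows; strand and truncation behavior is exercised
  exhaustively by the layout grid instead.
* **Replicate bins** are point-substituted copies (substitutions always
  change the base), so expected identity is exactly 1 − rate and the
  realized substitution count is recorded in the truth. The demo uses
  0.5% replicates (well inside the 98% boundary) and 10% decoys (well
  outside); boundary-rate behavior is documented, not asserted.
* **Abundance and depth.** Per-sample organism abundances are log-normal
  (σ = 1), normalized, with unbinned organisms pinned at 4×10⁻⁴ — far
  enough below the 0.1% rarity line that float noise cannot flip the
  classification. Depth is abundance × 1000 for *every* scaffold of a bin,
  which makes length-weighted and unweighted abundance estimates coincide
  and isolates the estimator under test.
* **Planted co-occurrence structure**: A1 and Group B hydrogenases are
  planted only in genomes that also receive an A3, and Rnf accompanies A3
  genomes with probability 0.75, so the co-occurrence fractions the
  pipeline reports have known expected structure by construction.

Not emulated: read-level data (no FASTQ; depth tables are generated
directly), sequencing error profiles, strain microdiversity within a bin,
chimeric binning errors, horizontal transfer, or any correlation between
gene content and abundance. Passing tests therefore demonstrate the
correctness of the decision rules and accounting on well-formed inputs,
not robustness to assembly or binning artifacts in real data.

Problem sizes used by the shipped demo and checks — 20 bins of ~36 kb
across 3 scaffolds, 4 samples, ~1,500 proteins, a 624-layout operon grid,
10,000 random proteins for the scan oracle — were chosen so the whole
suite and the acceptance script each run in well under their two-minute
demo budget on one CPU while keeping every statistical margin (binomial
error on mutation rates, lognormal abundance spread) far from the decision
boundaries being tested.

## Determinism and numerical conventions

All randomness flows through `numpy.random.default_rng(seed)`; identical
arguments give byte-identical FASTA/TSV/JSON outputs. The pipeline summary
is written with sorted keys and no timestamps, and the demo's expected
summary is derived from the planted truth by an independent code path, so
"run twice, compare bytes" is a meaningful test. TSV outputs carry the
seed in a header comment; coverage tables are parsed with round-trip float
precision. Ties are broken lexicographically everywhere a total order is
needed (profile names, cluster seeds, dereplication representatives), so
input order never changes any output.

## Known limitations

* Hydrogenase group identity trusts profile labels; without reference
  phylogenies, misassigned profiles propagate.
* The pairwise-identity estimator assumes collinear, mostly-complete
  bins; heavy fragmentation or rearrangement would undercount the aligned
  fraction (real surveys use a whole-genome aligner here).
* The shipped pathway rulebook is a minimal marker reconstruction, not a
  curated ortholog set; absence calls are only as good as the upstream
  profile search.
* Completeness/contamination use the plain counting estimator; figures
  are not comparable to lineage-aware tools without recalibration.
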