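# Methods

`allobarcode` implements a multi-locus DNA-barcoding analysis for a species
triangle consisting of two diploid parents and their derived allotetraploid
— the configuration exemplified by *Brachypodium distachyon* (2n = 10),
*B. stacei* (2n = 20) and *B. hybridum* (2n = 30).  This note describes the
models and procedures, the parameters that matter, what the synthetic-data
generator does and does not emulate, and the numerical choices made where
the design was open.

## Distance model and barcode gap

Pairwise divergence uses the Kimura two-parameter model.  For a sequence
pair, let `P` and `Q` be the proportions of transition (A↔G, C↔T) and
transversion differences over the columns compared; then

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q).

Columns carrying a gap or an IUPAC ambiguity code in either sequence are
excluded per pair (pairwise deletion, the MEGA default); complete-set
deletion — dropping every column that is not unambiguous across the whole
matrix — is available by flag.  Pairs whose substitution load makes a log
argument non-positive are *saturated*: they carry no finite distance, are
excluded from summaries, and are counted in the report rather than silently
dropped.  Group summaries report mean/min/max and, by default, the sample
standard deviation over pairwise values (population-style by option; the
convention behind published "(sd)" columns is rarely stated, so it is
configurable).

A locus shows a **barcode gap** for two groups when the smallest
inter-group distance exceeds the largest intra-group distance; the report
carries the numeric margin, so a marginal gap is visible as such.

**Site classification.**  A column is *variable* when it carries at least
two distinct unambiguous states anywhere in the matrix, and *diagnostic*
when every parent-A sequence is fixed for one unambiguous state and every
parent-B sequence for a different one.  Diagnosis is computed over the
diploid individuals only: allotetraploids carry both parental states and
would otherwise erase every diagnostic site.  Runs of gap columns fixed in
exactly one parent are reported separately as diagnostic indels
(half-open column intervals, 0-based) rather than as nucleotide sites.

## Haplotype networks

Identical aligned sequences collapse into haplotypes; gaps count as a fifth
character state, so a 6-bp fixed indel separates haplotypes by six steps
under the default literal rule (an optional recoding collapses a contiguous
gap run into one step).  Sequences with ambiguity codes are excluded from
collapsing (with a warning) under the default strict policy, the usual
practice for network construction.

The network is a minimum-spanning network: candidate pairs are processed in
increasing step order and a pair is connected when its endpoints are still
in different components at the start of its step level.  Because admission
is evaluated against the component structure of the *previous* level, every
alternative connection of equal minimal length is retained — these are the
loops typical of multicopy nuclear loci.  Multi-step connections are
materialised as chains of anonymous inferred intermediates, so every edge
in the emitted graph is exactly one mutational step.  Pairs further apart
than the connection limit stay in separate components.

The statistical-parsimony probability recursion that would derive the limit
from a 95% confidence level is deliberately not recomputed: published
analyses configure the cap (conventionally 30 steps for loci of this
length) rather than derive it per dataset, so `connection_limit` is a
direct parameter.  The uncapped minimum step count between the two parental
haplogroups is reported separately, since haplogroup separations can exceed
the display cap.

## Neighbor-joining discrimination

Trees are built with the Saitou–Nei agglomeration (scikit-bio's
implementation) from the K2P matrix.  Negative branch-length estimates —
possible on non-additive matrices — are clamped to zero with the deficit
moved to the adjacent branch, and the event is flagged.  Trees are
unrooted; "monophyletic" means one side of an edge-induced bipartition.  A
species is *discriminated* when strictly more than half (configurable) of
its individuals form a pure bipartition side.  An optional
column-resampling bootstrap reports per-group discrimination frequencies
(default zero replicates).

## The decision engine

Per-sequence parental-type calls score each sequence at the diagnostic
sites of its locus: a matching A or B state is one vote, gaps, ambiguities
and third states are silent.  A parental call requires vote purity ≥ 0.9;
the default tolerates 1–3 homoplasies on a ~30-site profile while rejecting
mosaic sequences.  Failing that, a breakpoint scan tries every split
between consecutive scoreable sites in both orientations; a split is a
*recombinant* call when each segment has ≥ 3 scoreable sites and ≥ 0.9
purity for its own (distinct) parent, and the best split beats the best
single-parent assignment by ≥ 2 matches.  The margin prevents a single
terminal homoplasy from masquerading as a breakpoint.  All three thresholds
are exposed in the configuration.

Per-individual verdicts combine loci in a fixed priority:

1. a nuclear locus showing both parental types — or a recombinant plus a
   parental type — is direct evidence of the combined genome → hybrid;
2. the plastid type contradicting a unanimous nuclear type betrays a
   hybrid whose nuclear copies converged to the non-maternal parent →
   hybrid;
2b. two nuclear loci unanimously fixed for *different* parents → hybrid
   (this keeps verdicts monotone: adding a locus can never demote a hybrid
   call);
3. concordance across plastid and all nuclear loci → that parent;
4. a single concordant locus cannot exclude a fully converged hybrid → the
   parental call with an `unconfirmed` audit flag;
5. anything else → ambiguous.

A hybrid that inherited its plastid from one parent *and* converged its
ribosomal arrays toward that same parent is indistinguishable from that
parent using the plastid + multicopy pair — the engine reproduces this
failure mode deliberately; it is the reason the single-copy locus earns its
place in the barcode.  Identification success is scored per true species
over samples carrying an informative call at every requested locus
(samples missing a locus leave the denominator; the policy is stated in the
report).

**Clone screening.**  When both homeologs are retained, observing them in a
clone sample is a two-color urn problem: with each clone drawing the
minority copy with probability `q`, the probability that `n` clones reveal
both copies is `1 - q^n - (1-q)^n`.  `clones_needed(q, p)` inverts this;
at `q = 0.5`, 6 clones give 95% detection, while a 9:1 copy imbalance
(`q = 0.1`) needs 29 — which is why occasional samples require screening
10–16 or more clones.

## The packaged survey table

`seqio.load_survey_table()` ships a 210-sample transcription of the
published haplotype-type survey of the *Brachypodium* triangle (56
*B. distachyon*, 43 *B. stacei*, 111 *B. hybridum*), with per-locus
haplotype identifiers typed as parent-A-like or parent-B-like, cloned-locus
flags, chromosome counts where recorded, and their evidence class
(`count` = counted in the originating survey, `literature` = taken from
prior reports).  A haplotype listed under both parental columns of one
locus is typed `recombinant`.  Running the decision engine on this table
reproduces the survey's headline figures at runtime: 96.2% of hybrid
plastid sequences are parent-B-type (102/106); hybrid ribotypes split
83.0% / 6.4% / 10.6% (78/6/10 of 94) into converged-to-A, converged-to-B
and both-retained; 96.8% of GI-surveyed hybrids (30/31) show both parental
homeologs; and the combined plastid+ITS rule identifies 89.1% (82/92) of
hybrids with both loci, every concordant fully-converged hybrid counting
as a miss.  The GI-only and plastid+ITS success rates are computed over
all surveyed hybrids carrying the required loci; restricting to
chromosome-counted samples is possible through
`identification_success(..., restrict_to=...)` but is not the default,
because the unrestricted denominators are the ones the published headline
percentages correspond to.

## Synthetic-data generator

The generator produces truth-labelled datasets with the statistical
structure the analysis assumes, so every stage is testable without
downloading accessions.  Defaults mirror the study conditions:

| parameter | default | meaning |
|---|---|---|
| loci | trnLF 782 bp / ITS 612 bp / GI 665 bp | plastid, nuclear-multicopy, nuclear-single-copy |
| `d_ab` | 0.024 / 0.055 / 0.038 | target inter-parental K2P per locus |
| `kappa` | 2 | transition:transversion count ratio |
| `theta` | 0.005 | expected intra-pool pairwise distance |
| sample sizes | 56 / 43 / 111 | parent A / parent B / hybrids |
| `maternal_from_b` | 0.962 | plastid drawn from parent B |
| `its_fates` | 0.83 / 0.064 / 0.106 | converge-to-A / converge-to-B / retain both |
| `single_copy_retain_both` | 0.967 | homeolog retention at the single-copy locus |
| `n_clones`, `q` | 5, 0.5 | clones sequenced; minority-copy draw probability |
| `recombination_prob` | 0.02 | single-breakpoint splice per nuclear locus per hybrid |

Parental divergence is planted as a fixed set of diagnostic differences on
a random ancestor; the count inverts the K2P expectation at `kappa` and
subtracts the intraspecific contribution, with a correction for mutations
that land on planted columns, so the expected inter-pool mean equals
`d_ab` (verified unbiased within three standard errors of the replicate
mean over 100 seeds).  Intra-pool diversity is haplotype-structured: each
pool holds five haplotype classes with geometrically decaying frequencies
(≈ 52/26/13/6/3%), each class carrying its own small calibrated mutation
set.  This mirrors selfing populations, where most individuals share a
common haplotype, and it is what keeps planted diagnostic sites largely
intact (~96% recovered at defaults) — the same total mutation mass spent
on per-individual private mutations would erode a quarter of them.
Randomized rounding of the planted-difference and per-class mutation
counts keeps all expectations exact.

Hybrids draw one gamete per parent per locus from the pool members (so
hybrid copies share parental haplotypes, as observed).  The plastid locus
emits the maternal gamete; the multicopy locus follows its sampled fate,
with conversion modelled as all-or-nothing per individual (partial
conversion and intra-array polymorphism are out of scope); the single-copy
locus keeps both homeologs with probability 0.967 and is observed through
`n_clones` clone draws; and with probability `recombination_prob` a
nuclear copy is replaced by a single-breakpoint inter-parental splice with
a uniform breakpoint, recorded in the truth table.

What the generator does *not* emulate: coalescent genealogies and
incomplete lineage sorting, rate heterogeneity across sites, a spontaneous
indel process (planted fixed gap runs are available by option), sequencing
error and chromatogram artefacts, and geographic structure.  Passing tests
on synthetic data therefore demonstrate the correctness of the machinery
and the calibration of the generator — not that real populations satisfy
the generator's assumptions.

A single integer seed drives a `numpy` `SeedSequence` that is split per
stage (one stream per locus pool, one for hybrid structure), so
regeneration is bit-identical for a given seed and parameter set.

## Numerical and design choices

- Alignment coordinates are 0-based; all intervals are half-open.
- Input residues are case-normalised to uppercase; `U` maps to `T`; IUPAC
  ambiguity codes are stored but excluded from distances (pairwise
  deletion), from haplotype collapsing (strict policy), and cast no vote in
  type calling.
- NJ tie-breaks follow scikit-bio's deterministic agglomeration order;
  network tie-breaks order candidate pairs by (steps, id, id).  Reruns with
  the same inputs and seed are identical.
- Breakpoint-scan ties resolve to the leftmost best split; the reported
  breakpoint is the alignment column of the first right-segment site.
- Degenerate inputs fail loudly: ragged alignments, empty pairwise
  overlaps, saturated pairs entering tree building, groups with fewer than
  two members (intra statistics are reported as undefined, never zero).
- The pipeline's canonical report is JSON; tab-separated views are derived
  from it.  Every reported number equals the corresponding module-level
  call on the same inputs.

## Problem sizes used in the test suite

Oracle tests run on small instances where brute force is exact: networks
up to 6 haplotypes × 8 columns against an independent minimum-spanning
oracle, NJ on additive matrices up to 8 taxa, monophyly against a full
bipartition scan up to 12 leaves, clone-detection probabilities against
exhaustive 2^n enumeration up to n = 12.  Calibration tests use 100
generator replicates at the default (study-sized) diploid pools and 500
hybrids for the fate fractions; the full suite completes in well under a
minute.

## Known limitations

- K2P assumes equal base frequencies and two rate classes; for these loci
  at these divergences the approximation is conventional rather than
  critical.
- The recombinant scan models exactly one breakpoint; double crossovers
  and gene-conversion tracts shorter than `min_segment` diagnostic sites
  are not called.
- Diagnostic-profile calling presumes the query is aligned to the same
  coordinate frame as the profile; no re-alignment is attempted.
- The survey transcription records haplotype *types*, not sequences, so
  survey-driven verdicts exercise the decision engine but not the
  sequence-level callers (those are exercised on synthetic data).
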