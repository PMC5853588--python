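# Methods

This note records the statistical model, the simulation design, the
numerical choices, and the limitations of `orgedit`.

## Editing-extent model

At each annotated C target the data for one sample are the numbers of reads
whose base at the target, read on the transcript's sense strand, is T
(edited), C (unedited), or anything else (other). The editing extent is the
binomial proportion `E = edited / (edited + unedited)`; "other" calls are
sequencing or alignment artifacts and are excluded from the denominator, so
E is a proportion over the two informative bases. E is undefined (NaN, and
the site is `not_assayed`) when the informative depth is zero.

Pileup quantification from SAM follows the library's strand- and
transcript-specific construction: only alignments on the transcript's sense
strand are counted (for a '-' strand transcript the sense bases appear
reverse-complemented on the forward reference, so edited U reads as A and
unedited C as G). A read must align an actual base at the target — a
deletion or reference skip contributes nothing — with at least
`min_base_anchor` aligned bases on each side (default 3, a guard against
terminal misalignment at the target).

## Differential test

For a wildtype/mutant contrast with r1 and r2 biological replicates, every
replicate pair is compared with the 2x2 Pearson chi-square on
[[e1, u1], [e2, u2]] (1 df, closed form N(ad−bc)²/((a+b)(c+d)(a+c)(b+d));
Yates continuity correction available but off by default, since the plain
Pearson statistic is the conventional choice at these depths). A zero row
or column margin carries no evidence and is defined as statistic 0, p 1.

A site is called only if **all** pairwise tests (four in the 2+2 design)
are below `alpha_nominal = alpha_family / n_tests` with a *strict*
inequality, and the extent difference Δ = E_mutant − E_wildtype reaches the
effect floor `min_delta = 0.1`. `n_tests` defaults to the number of assayed
sites in the current run (612 in the reference design, giving
1e-3/612 ≈ 1.6e-6), so the family-wise level generalises beyond the
reference site catalogue. Δ is computed from pooled replicate counts by
default; a mean-of-replicate-extents mode is provided because either
convention is defensible, and they differ only under unequal depths.

The intersection-of-tests rule is conservative by design: under the null
the chance that all four dependent tests pass at `alpha_nominal` is itself
at most `alpha_nominal` (the tests share replicates and are positively
dependent; verified by simulation in the test suite), so the family-wise
false-call rate over 612 sites stays well below `alpha_family`.

A depth floor (`min_depth`, default 100 informative reads per replicate per
site) marks sites `not_assayed` rather than feeding near-empty tables to
the chi-square. Assayed-site counting for the Bonferroni divisor happens
after this filter.

## Complementation

Each transgenic line is a single plant; it is tested against every
replicate of its background mutant and all tests must pass — mirroring the
replicate-intersection logic (the conservative reading; the per-pair rule
is configurable through `TestConfig`). The expected direction at a
mutant-affected site is the opposite of the mutant defect. The
complementation effect CE = (E_T − E_M)/(E_WT − E_M) uses pooled wildtype
and mutant counts, consistent with the pooled Δ mode; it is undefined when
E_WT = E_M (no defect to rescue) and flagged transgressive strictly above 1.
With two transgenic lines per background, mutant-affected sites partition
into both / only-one / neither responded; invariant sites that move
significantly in the transgenics are tallied separately by direction, since
overexpression of an inhibitory factor is expected to push otherwise-stable
sites down.

## Splicing

Splicing efficiency is `spliced/(spliced+unspliced)`. From alignments:
spliced reads carry a reference skip equal to the annotated intron exactly
(tolerance configurable, default 0 — synthetic alignments are exact, and
real spliceosomal boundaries are fixed) with ≥ `anchor` aligned bases on
each flanking exon; unspliced reads are ungapped and span an exon-intron
boundary with ≥ `anchor` bases on both sides (default 6). Both boundaries
contribute to the unspliced count; in the toy intron model the intron
(300 nt) is longer than a read (100 nt), so one read can span only one
boundary and the spliced fraction of junction-informative reads is an
unbiased binomial estimate of the true efficiency. The same ratio accepts
non-integer relative expression levels from a junction-specific qRT-PCR
pair. Genotype comparisons report means ± SD and a Welch t statistic,
explicitly flagged descriptive-only: with two biological replicates it has
one degree of freedom and is a display statistic, not an inference.

## Synthetic-data generator

The generator defines the reference study conditions: 612 sites (576
mitochondrial + 36 plastid) over 24 mitochondrial transcripts drawn from a
pool of real organellar gene names with their complex assignments; two
biological replicates per genotype; binomial read counts; one intron model.
Sites are spaced 400 nt apart on a toy reference so a 100-nt read covers
exactly one site, which makes pileup totals match the drawn counts exactly.

Truth construction: wild-type extents are uniform on [0.2, 0.9] (most real
organellar sites are substantially edited; the band leaves room for effects
in both directions). Effect classes are assigned to `round(frac x n)` sites
(half away from zero — the rounding used for printed percentages), default
fractions 14% increased / 3% decreased among mitochondrial sites, matching
the observed prevalence of each direction; effect sizes are uniform on
[0.15, 0.4] and base extents are redrawn inside the feasible band so
clipping to [0, 1] can never shrink a planted effect below the 0.1 floor.
Counts are `Binomial(depth, extent)` with depth 2000 by default — the 2x2
chi-square assumes binomial sampling, so the generator's default matches
the test's model; a beta-binomial dispersion option exists purely for
robustness testing, and an error-rate option diverts a binomial share of
reads to "other".

What the generator does *not* emulate: PCR amplification bias, per-site
depth variation within a sample, quality scores, alignment error, linked
sites on a shared amplicon. Passing tests therefore demonstrate that the
statistics are implemented correctly and behave as designed under their own
sampling assumptions, not that real libraries are free of overdispersion;
with real data the binomial assumption should be checked (the dispersion
knob exists to probe the consequences).

## Problem sizes and determinism

Every stochastic stage takes a seed and is byte-reproducible for fixed
inputs. The acceptance script runs the full 612-site study at depth 2000,
200 all-invariant batches at depth 1000 for the type-I measurement, and
10 000 junction reads per splicing sample; these sizes give binomial
standard errors a factor of several below every margin being checked while
keeping a complete run in seconds. Derived seeds come from a
`SeedSequence` spawn of the user seed and stay below 2^31.

## Known limitations

- The classifier treats replicates as exchangeable binomial samples; batch
  effects between replicates inflate the pairwise statistics symmetrically
  and the intersection rule only partially protects against them.
- The both/one/neither partition assumes exactly two transgenic lines per
  background; with one line a reduced partition is reported with a note.
- The intron module models a single cis-spliced intron; multi-part
  trans-spliced transcripts are out of scope.
- `chisq_independence` drops zero-marginal rows/columns rather than
  collapsing categories; with very sparse tables the user should collapse
  to the 2x2 affected-vs-invariant form (`collapse_to_affected`).
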