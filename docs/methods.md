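# Methods

`barkit` models the computational side of building and analysing a
barcode-tagged random-insertion mutant library in fission yeast: the
insertion cassette and its interrupted barcode, the SfiI
concatemerization census, the library-design arithmetic, and in-silico
prediction of four insertion-site mapping strategies over simulated
insertion alleles. This note records the models, the defaults and why,
and what the synthetic data do and do not show.

## Double-stranded DNA and the ligation rule

Sequences are stored as a top strand (5'→3') plus explicit sticky-end
metadata on fragments: overhang kind (blunt / 5' / 3') and the
protruding single-stranded bases read 5'→3' along their own strand. In
this representation each protrusion lives on exactly one fragment's top
strand, so ligation is plain concatenation and digestion/ligation are
exact inverses. Two ends are ligatable iff both are blunt, or they have
the same kind and equal-length protrusions that are exact reverse
complements (antiparallel annealing). Everything directional in the
census workflow follows from this single predicate: a 3-nt 3' overhang
can never equal its own reverse complement (odd length), so monomers cut
with SfiI (GGCCNNNNNGGCC, cut 8/5) can only chain head-to-tail when
the two spacers share their middle three bases. The default spacers are
both `AGGTT`, giving monomer protrusions ACC/GGT.

Digestion is always complete (the protocols modelled drive digests to
completion); star activity, methylation and kinetics are out of scope.
An `N` in a sequence never matches a concrete pattern position, so
unknown bases cannot create phantom sites. Coordinates are 0-based
half-open internally and 1-based inclusive in written reports.

## The cassette

Element order (5'→3'): 250 bp ATG-less lambda buffer, 240 bp
lexA-HSP70 promoter stand-in, SfiI site, 6 bp pad, 41 nt barcode, 6 bp
pad, SfiI site, 34 bp lox71, 1497 bp ura4 stand-in; 2100 bp total. The
excised barcode monomer is exactly 66 bp (the distance between the two
SfiI site starts), and the census amplicon is 760 bp with 197/497 bp
flanks, matching the workflow's gel arithmetic. Filler elements are
seeded pseudo-random stand-ins constrained to length, to zero ATGs on
the transcribed strand (buffer), and to freedom from the workflow's
restriction and degenerate-primer sites; the real element sequences are
not part of the model. The ura4 stand-in carries exactly one planted
EcoRV site (offset 1000) because the inverse-splinkerette method
requires an enzyme that cuts the vector once.

The barcode mask is `(NNA)×13 + NA`: 27 random positions, 14 fixed
A's, length 41. The exact fixed positions are a design choice (the
counts, not the positions, are constrained); the mask is a single
config value read by both the generator and the parser. Random barcodes
are rejection-sampled against creating any workflow restriction site in
cassette context — about 1–2% of raw draws would otherwise contain a
chance SpeI/XbaI/EcoRV site inside the random positions and silently
break the mapping chemistry.

## Concatemer census

Chain lengths are truncated-geometric with extension probability 0.69,
calibrated once so that the 0.3–1 kb size-selection window (5–15
monomers at 66 bp) yields a mean of about seven barcodes per cloned
concatemer, the routine yield of the emulated protocol. Parsing splits
a read at SfiI junction motifs, tolerating one substitution among the
eight constant junction bases, and requires candidates to sit on the
66-bp monomer grid — the interrupted design exists precisely so the
parser has fixed anchors. Each segment's 41-nt window is scored against
the mask; when left- and right-anchored windows disagree equally well
the call is `ambiguous`, never a guess, and unparseable segments are
`fail` calls rather than silent drops. The read simulator is
substitution-only (truncation at 900 nt by default); indels produce
fail calls by design.

Census collapse is directional: after an exact tally, each barcode is
absorbed into the highest-count retained barcode within edit distance 4
whose count is at least twice its own, processing smallest-first with
lexicographic tie-breaks (deterministic, order-independent, count-
conserving). Radius 4 was chosen from the error model: at a 1% per-base
substitution rate roughly one call per thousand carries three or more
errors and would survive a smaller radius as a spurious singleton,
while genuine 41-nt barcodes are pairwise ~30 edits apart, so radius 4
cannot merge distinct tags in any realistic library. Proportions use
Wilson score intervals (stable at the small n of the printed colony
counts); abundance change is a pseudocount-regularized log2 ratio of
proportions with configurable flags (the depletion threshold −2 is a
default, not a derived quantity).

## Library-design mathematics

Coverage uses the sampling equation P = 1 − (1−f)^N for a gene of
genome fraction f under N uniform insertions (evaluated via `log1p` /
`expm1`); its inverse returns the smallest integer N reaching a target.
Expected phenotype-class counts are N × (k_class/k_total) ×
coding_fraction with half-up rounding (reproducing the published
integer from 37.46). Barcode uniqueness is reported under both
readings: per-mutant (1 − 1/K)^(N−1) — the reading under which the
≥95% design bound holds at N = 1% of K = 1.86×10^5 — and the
library-wide birthday product ∏(1 − i/K), computed in log space, which
is orders of magnitude smaller at the same operating point. Both are
surfaced deliberately.

## Insertion alleles and mapping predictors

An allele is an ordered list of cassette copies (orientation plus
left/right end trims), an optional mitochondrial co-integrant placed 5'
of the first copy, and a small genomic deletion at the insertion point.
Every spliced base keeps a provenance record (source contig/copy,
source coordinates, strand), which gives exact length bookkeeping and
lets the predictors reason about what a sequencing read would show.

PCR is primer-site geometry plus a product-length cap (default 3 kb;
5 kb for the circularized inverse-splinkerette product), not
thermodynamics. TAIL-PCR's annealing-temperature alternation is
abstracted into the AD-primer match rule: full IUPAC match with a
concrete 8-nt 3' anchor. Three nested vector primers sit in the
constant promoter element pointing at the buffer end; nesting is
enforced by requiring each round's product to contain the next round's
site. The shortest surviving product wins, and its outcome is the kind
of the first non-vector sequence the read meets beyond the vector end:
nuclear → `genomic_junction`, mitochondrial co-integrant →
`mito_cointegrant`, none within the product → `vector_only`. This
"what the electropherogram shows" rule is what makes head-to-head
arrays deterministically vector-only (the vector primer binds both
strands and the internal product is shortest) and 5'-side co-integrants
deterministically mitochondrial.

Splinkerette digestion uses SpeI+XbaI (both leave CTAG, one adaptor),
and the product runs from the nested vector primer across the buffer
end to the nearest compatible cut plus a 30-bp adaptor. Inverse
splinkerette walks each copy with an intact marker-primer/EcoRV region:
the fragment from the copy's internal EcoRV cut across its buffer end
to the neighbouring cut circularizes (cap 20 kb), SfiI relinearizes it
at the buffer-side site, and the nested marker primers read across the
re-ligated EcoRV junction — so the first sequence shown is whatever
lies at the neighbouring cut, and the reported interval is bounded by
that cut. When that distance is within `exact_threshold` (30 bp) the
junction itself is visible and the result is exact. Cre–lox
integration swaps lox arms in the spacer: lox71 × lox66 yields one
wild-type loxP and one double-mutant hybrid, ordered hybrid-first along
the chromosome; the hybrid+loxP pair is treated as Cre-inert, making
integration one-way, and a second exposure is a logged no-op. Flank
cloning digests the integrated locus, requires origin and marker on one
cut-free fragment, and re-circularizes it (intramolecular ligation
assumed to succeed under the cap).

Reported intervals whose edge is an observed junction are widened by
the configured residual genomic-deletion bound (default 5 bp, the
design's deletion ceiling) so that an allele which deleted a few bases
still has its pre-insertion coordinate inside the interval; this is the
honest uncertainty of the method, and `exact_junction` is only claimed
for width ≤ 1.

## Synthetic data: what it emulates and what it does not

The toy genome is three 120-kb nuclear chromosomes plus a 20-kb
mitochondrial contig — a deliberate desk-scale stand-in that preserves
the statistics the formulas and workflows use: ~57% (±3%) of the
nuclear sequence in non-overlapping gene features of mean 2 kb (5%
ncRNA), and guaranteed landmark densities (EcoRV every 3 kb, SpeI/XbaI
every 2.4 kb, AD-primer site pairs in both orientations every 1.5 kb
nuclear / 1.0 kb mitochondrial — the mitochondrial spacing sits below
the minimum co-integrant span so a co-integrated fragment always offers
a primer partner). Chance SfiI sites are scrubbed from the genome
because a genomic SfiI cut inside the inverse-splinkerette circle is
not part of the modelled chemistry. Base composition is otherwise
uniform: no GC skew, repeats, or real *S. pombe* homology. Passing
recovery tests therefore demonstrates the correctness of the
algorithms and the internal consistency of the chemistry — not
performance on real genomes, where repeat content and site-density
fluctuations would add failure modes the generator does not produce.

Library simulation draws insertion positions uniformly over nuclear
contigs (6 kb from the edges), structures from the configured mix (15%
single, 55% tandem head-to-tail of 2–4 copies, 7.5% + 7.5%
head-to-head and tail-to-tail pairs, 15% co-integrant), vector-end
trims of 5–60 bp (85%) or 61–1800 bp otherwise — the copy that must
keep the selectable marker caps its buffer-side trim at 550 bp and its
marker-side trim at 60 bp, since deeper marker resection would not
survive selection — and 0–5 bp genomic deletions. Every mutant records
a machine-readable truth record; recovery tests read truth only from
those records. All generators are pure functions of (spec, seed).

## Problem sizes and numerical choices

Default test and acceptance runs use the desk-scale sizes above: 1000
concatemer round-trip trials, 300-read error simulations, 200-mutant
mapping panels, 10^5-draw Monte-Carlo cross-checks — sizes chosen so
the whole suite completes in well under a minute on one core while
keeping binomial 3-s.d. bands tight enough to be informative.
Probability code works in log space (`log1p`, summed logs for the
birthday product) to avoid underflow at realistic K and N. Degenerate
inputs are contractually handled: zero restriction sites return the
input unchanged, empty reads parse to empty call lists, n = 0
proportions and P_target = 1 sizing raise domain errors.

## Known limitations

- Partial digestion, methylation and enzyme kinetics are not modelled.
- PCR yield, mispriming thermodynamics and chimera formation are not
  modelled; the predictors return geometry-feasible products only.
- The concatemer parser guarantees apply to substitution errors;
  indel-bearing reads degrade to fail/ambiguous calls.
- Co-integrants are placed 5' of the first cassette copy; other
  arrangements occur in real alleles and would shift which method
  observes them first.
- Stand-in element sequences mean no claim is made about promoter
  activity, marker function, or homology-driven artefacts.
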