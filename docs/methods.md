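# Methods

This note documents the models, conventions and numerical choices
behind `carhscan`, and what the synthetic-data generators do and do not
emulate.

## Coordinates and promoter windows

Genomic coordinates are GFF3-style: 1-based, inclusive.  Promoter
positions are numbered in gene frame with +1 the first base of the
annotated start codon and -1 the base immediately upstream; there is no
position 0, following the standard promoter-numbering convention.  The
default window spans -150..+25 and therefore contains 175 bases.
Windows are always reported 5'→3' on the coding strand (minus-strand
windows are reverse-complemented genomic slices).  Windows clipped by a
contig edge are returned with a `truncated` flag rather than rejected,
because draft-genome annotations often sit near contig boundaries.

## Repeat patterns and the scanner

Operators are runs of abutting 11-bp direct repeats.  Published
descriptions of the repeat exist in two notations — a search grammar
`N4-T-N3-C[C][G]` / `N4-T-N2-RCR[G]` and a body consensus
`nnnnTnnACAn` — which disagree at positions 10-11 if the bracketed
bases are read as fixed.  We adopt nested defaults that are consistent
with both readings:

| pattern   | constraints (1-based position within the 11-mer)  |
|-----------|----------------------------------------------------|
| loose     | T at 5, C at 9                                     |
| strict    | T at 5, R at 8, C at 9, R at 10 (R = A/G)          |
| DR label  | T at 5, A at 8, C at 9, A at 10 (TnnACA core)      |

so that DR ⊂ strict ⊂ loose by construction.  A "methods-literal"
preset treating the bracketed bases as fixed is shipped and selectable
(`--preset methods-literal`); the choice is logged.  All constraints
are configurable per position.

The scanner reports every maximal run of contiguous (step exactly 11,
i.e. abutting; a nonzero gap is not part of the model) loose-matching
11-mers with at least `min_repeats` (default 3) units and at least
`min_strict` (default 1) strict matches.  Runs overlapping in different
registers are resolved deterministically: most strict matches first,
then most DR labels, then leftmost.  Scanning is on the coding strand
only by default, matching an upstream-region search.  `N` bases never
satisfy a constrained position.

Probabilistic PWM scoring is deliberately out of scope: the search is
pattern-based, and the PFM builder exists to export count matrices and
consensus strings (IUPAC codes on ties) for external logo rendering.

## Protein motifs and classification

Motifs are degenerate patterns with fixed residues, alternatives and
bounded-length spacers: `Wx9EH` (12 residues), `RxWERRY` (7), and the
B12-binding motif `[D/E]-x-H-x2-[G/P]-x41-S-x-[T/V]-x(22..27)-G-G`.
Spacer bounds default to exactly the printed values (x41 exact, no
slack); the matcher explores every admissible spacer length and allows
overlapping hits.  `X` in a query is tolerated but never matches a
fixed residue.

Classification is by motif co-occurrence: a sequence without the
B12-binding motif is `non_member`; with it, the presence of an intact
Wx9EH makes it `CarH`; otherwise presence of RxWERRY makes it `CarA`;
otherwise `ambiguous`.  We do not attempt to detect the residual E-H
pair of a degenerate Wx9EH in CarA — a two-residue anchor is too common
to place without a structural alignment — absence of the intact motif
suffices.  A protein length outside 286-330 aa (the homologue
acceptance range) is flagged but still labelled.  Database E-values are
not computed (no database search is performed); instead, when
reference sequences are supplied, a >=29% best-identity filter is
applied.

The DBD/CBD boundary is not derivable from sequence alone; we use a
declared heuristic — end of the RxWERRY hit plus a 30-residue wing
allowance, capped so the CBD is non-empty — configurable via
`split_domains(wing_allowance=...)`.

Percent identity uses Biopython's `PairwiseAligner` in global mode with
BLOSUM62, affine gaps (open -11, extend -1) and free terminal gaps;
identity = identical columns / columns between the first and last
aligned pair (internal gaps count in the denominator).  The aligner's
first reported alignment is used, which is deterministic run-to-run;
the test suite verifies optimality of its score against an independent
Gotoh dynamic program.

## Cooperative binding model

A repressor dimer engages two contiguous intact repeats (one per DBD);
a "partial" placement engages a single repeat with one DBD.
Enumeration of non-overlapping placements up to `max_dimers` is
exhaustive.  Band categories: `double` when two full dimers fit
simultaneously (needs >=4 usable repeats), `single_plus_weak_upper`
when one full dimer can be joined only by a partial one (3 contiguous
intact repeats), `single` for an isolated tandem pair, `none` when no
tandem intact pair exists.  Partial placements never count toward the
stable double band — they only explain the weak upper band on
three-repeat probes.

Footprints: each engaged repeat contributes one protection tract per
strand, default 3 nt wide (observed tracts are 2-3 nt), centred on the
repeat's sixth base, so adjacent engaged repeats give centres 11 nt
apart.  The DNase I span is the engaged-repeat union plus a 4-nt margin
per side.  Exonuclease III stops default to +4 nt downstream of the 3'
edge (sense strand) and -3 nt upstream of the 5' edge (antisense, the
midpoint of the observed 2-4 nt range); both are configurable, since
experiment gives ranges rather than single offsets.  Strong vs weak
arrest is categorical and not modelled quantitatively.

## Hill fitting

EMSA fraction bound is `1 - I_free/I_free,0`, clipped to [0, 1].  The
3-parameter Hill model `f = A·c^h/(K_D^h + c^h)` (free amplitude rather
than a baseline offset) is fit by bounded least squares
(`scipy.optimize.curve_fit`) with fixed, deterministic initialisation:
A0 = max(f), K_D0 = the concentration nearest half of A0, h0 = 1;
bounds A ∈ (0, 1.05], K_D > 0, h ∈ (0.1, 6].  On noise-free synthetic
curves the fit recovers (A, K_D, h) to three significant figures across
K_D ∈ {5, 35, 200} nM × h ∈ {1, 2, 3}; with additive noise σ = 0.03 at
the seven-point titration series the median K_D error over 200
replicates is below 10%.

## SEC calibration and oligomer calls

The column calibration is the log-linear line
`log10(Mr/Da) = 8.1537 - 0.2316·Ve(ml)`.  Units are an adopted
reading — log base 10, Mr in daltons, Ve in millilitres — which yields
plausible masses (≈30-240 kDa) over the working range of an analytical
10/30 gel-filtration column; both constants and the calibrated Ve range
(default 8-20 ml, warning outside) are configurable.  The oligomeric
state is the nearest positive integer to apparent/protomer mass, with a
±25% default tolerance flag reflecting the accuracy of SEC mass
estimates.

## Expression normalisation

qRT-PCR tables are reduced by delta-delta-Cq: per-sample
ΔCq = Cq_target − Cq_reference (reference gene, e.g. rpoD), fold
change `2^-(ΔCq − mean ΔCq of baseline)` relative to a required
baseline condition (dark with B12 present in the motivating assays),
with mean and standard error over replicates.

## Synthetic data: what it emulates and what it does not

Generators are pure functions of (parameters, seed) using NumPy's
PCG64; identical seeds give identical outputs.

* `gen_promoter` plants a specified arrangement of DR/dr/mutated
  11-mers at a seeded offset in a GC-matched window (default GC 0.68,
  the midpoint of the 66-75% genomic range of the motivating clade).
  dr units carry exactly one core mismatch by default (configurable
  1-2) so dr-vs-background is unambiguous; mutated units break even
  the loose pattern.  Backgrounds are rejection-sampled until the
  scanner reports exactly the planted truth, so tests can assert exact
  ground-truth closure.
* `gen_protein` draws lengths uniformly from 286-330 aa and plants
  RxWERRY, then Wx9EH (Trp substituted for CarA, absent entirely for
  non-members) and the B12 motif with randomised spacer lengths.
  Background residues exclude W/E/H (and S/T/V/G/D/P by alphabet
  choice), so spurious motif matches cannot arise — which also means
  the generator does not emulate near-miss decoys or real amino-acid
  composition.
* `gen_emsa_curve` adds Gaussian noise (σ configurable, 0.03 in the
  simulated demo — a declared default, as no empirical noise magnitude
  is available) and clips to [0, 1].
* `gen_sec_trace` places Gaussian peaks at the elution volume the
  calibration assigns to n × protomer mass.
* `gen_mini_genome` stitches per-gene windows (each independently
  rejection-sampled) into a single contig with genes on alternating
  strands and GC-matched filler.

Because backgrounds are rejection-sampled clean and planted signals are
exact, passing tests demonstrate correctness of the algorithms under
the stated model, not robustness to the degenerate, overlapping and
partially conserved sites of real GC-rich genomes; the scanner's
behaviour on real data depends on the pattern preset chosen.

## Problem sizes and determinism

Property suites run the scanner against an exhaustive
all-offsets/all-registers oracle on 500 windows of 175 nt, the motif
matcher against a sliding-window oracle on 1000 proteins of 90 aa,
pattern nesting over all 4^6 variable cores, Hill recovery over a 3×3
parameter grid plus 200 noisy replicates, and generator closure over
100 seeded runs — sizes chosen to keep the default suite fast while
exercising every code path.  All randomness flows through explicit
seeds; there is no global random state.
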