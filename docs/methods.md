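# Methods

## Data model

All coordinates are 1-based inclusive genome positions on the S288C
reference. Genotype tables are tab-separated with one row per polymorphic
marker (`chrom`, `index`, `Ali_pos`, `S288C_pos`, `type` ∈ {S, I, D}, then
one 0/1 call column per cell). The alignment-position column is read and
carried but never used in computation. Call value 1 is the S288C (parent 1)
allele and 0 the SK1 (parent 2) allele. Octad tables carry eight call
columns ordered spore-wise as (mother, daughter) pairs; chromatid *i* of the
meiosis is columns 2*i* and 2*i*+1, and this ordering is part of the file
contract because heteroduplex detection is exactly "mother ≠ daughter for
the same spore". Missing calls are tolerated up to a configurable per-marker
fraction (default 0 — synthetic data is complete); markers beyond it are
dropped with a logged warning, and uncallable markers are transparent to
tract building (runs extend across them).

## Segregation calling and tract segmentation

Each marker's ordered cell-allele vector (its *signature*) yields the strand
ratio `a:b` with the parent-1 count written first. The octad token `4:4*` is
reserved for a balanced ratio with a non-empty heteroduplex set (symmetric
hDNA). Tract boundaries are defined by *signature equivalence*, not ratio
equality: two adjacent 5:3 runs whose minority allele sits in different
cells are different tracts. This distinction is what separates the trans
hDNA `5:3_5:3*` from a single continuous half conversion, so it cannot be
an implementation detail. Equal-ratio tracts with distinct signatures
receive distinct distribution ids in order of first appearance.

## Event calling

The parental *phase* — the chromatid-to-parent assignment — is read off
Mendelian background tracts (4:4 with empty heteroduplex set in octads, 2:2
in tetrads) and is piecewise constant. The calling rules are:

1. markers segregating 4:0 chromatid-wise (8:0 strand-wise) are of mitotic
   origin and removed before calling;
2. every maximal cluster of consecutive non-Mendelian tracts becomes a
   candidate event; every phase junction between adjacent Mendelian tracts
   without an intervening cluster becomes a transfer-less CO candidate;
3. events whose boundary-to-boundary distance (outermost affected markers;
   the junction midpoint for transfer-less COs) is below 5 kb are combined
   as products of one DSB — except that a conversion on a chromatid not
   involved in the nearby CO stays separate;
4. after merging, an event's kind is settled by the *net* phase across it:
   different flanking phases make a CO, identical phases a NCO. This single
   rule handles both the alternating wild-type CO pattern
   `3:1_2:2_3:1_2:2_3:1` (net change) and the NCO pattern `3:1_2:2*_3:1`
   whose interior Mendelian patch matches neither flank (net identity). A
   consequence worth noting: a same-pair double CO closer than 5 kb merges
   into a phase-neutral event and is reported as one NCO — with marker
   spacing two orders of magnitude below the merge distance this is the
   faithful reading of "arisen from the same DSB";
5. NCOs supported by a single non-Mendelian marker are discarded. The rule
   is applied to NCOs only: a CO is identified by its flanking phase change,
   not by its conversion markers, and transfer-less COs are a real, retained
   class.

A CO junction's position is the midpoint between the last left-phase and
first right-phase Mendelian markers. Tract and event lengths use midpoints
of flanking inter-marker intervals; at a chromosome end the boundary falls
back to the terminal tract marker (logged). An event's strand-transfer
length is the sum of its constituent 5:3, 6:2 and 4:4 patch lengths, which
for contiguous patches equals the midpoint-extended span.

Pattern rendering: within an event the first distinct signature per ratio
class is unstarred and each subsequent distinct signature gains a star;
interior Mendelian patches are starred only when they match neither flanking
phase; the aberrant octad 4:4 is always rendered `4:4*`. Canonicalization
under global parent swap (every `a:b` → `b:a` when the first unbalanced
token has its larger count first) makes patterns comparable with printed
inventories, which are orientation-normalised.

Chromatid involvement: heteroduplex chromatids come from the signature; a
homoduplex chromatid counts as converted only when its allele differs from
the local phase on *both* sides of the event, because at a CO an allele
matching either flank may simply reflect the arm exchange. Two-chromatid
events are split into sisters/non-sisters using the left-flank phase;
events touching three or more chromatids are retained with summary `multi`
and classify as "other".

## Classification rules

NCO classes (tested in the order trans, SDSA-like; the rule sets are
disjoint, the order just makes ties deterministic):

* **SDSA-like** — single chromatid, ≥ 1 half-conversion tract, all half
  conversions share one distribution, terminal tracts are half conversions,
  one asymmetry direction throughout (interior full conversions included),
  no aberrant 4:4*. *Canonical* iff the whole pattern is one tract.
* **trans** — as above with exactly two half-conversion distributions.
  *Canonical* iff the pattern is exactly `X_X*`.
* **other** — everything else.

Three inventory rows are rule-discordant with their printed grouping
(`5:3_4:4_5:3*_6:2_5:3*` is trans by these rules; `3:5_2:6_4:4_3:5` and
`3:5_4:4_3:5_2:6_3:5` are SDSA-like) — the original manual curation
evidently used information beyond the pattern string. The classifier follows
its stated rules; the fixture rows carry the printed grouping so both views
are testable, and the test-suite asserts exactly this three-row discrepancy.

CO classes: `no_transfer`; `single_chromatid`; two-non-sister events are
DSBR-compatible when the transfers on the two chromatids do not overlap
(an aberrant 4:4* is the pattern-level signature of overlap), flagged
asymmetric when the longer/shorter transfer length ratio reaches the
configurable threshold (default 3 — "clearly asymmetric" is not quantified
anywhere, so the default is a deliberate, visible choice); overlapping
transfers go to `two_non_sister_other`. Without tract geometry (printed
inventory rows) the overlap test falls back to the pattern alone and
asymmetry is not assessed.

## The simulator

The simulator is the package's ground-truth instrument: it writes strand
transfers at the level of the eight strands and logs every tract, so caller
properties become testable statements instead of plausibility arguments.

Pathways and their written states (all tract intervals in bp, DSB at x):

* `simple_SDSA` — one hDNA tract on one strand of the broken chromatid, on
  one side of x (fair coin); the invading-end hDNA on the other side is
  recorded as *transient*: invisible in octads, but convertible by MMR.
* `double_SDSA` / `dHJ_dissolution` — hDNA tracts on opposite strands of
  the broken chromatid meeting at x (the DSB sits at the boundary between
  the trans hDNA patches). Dissolution additionally restores a central
  patch with probability `p_nick` (an unligated nick priming nick
  translation), producing `5:3_4:4_5:3*`.
* `dHJ_resolution_NCO` — hDNA on both non-sister chromatids, one side each,
  opposite apparent directions, no arm exchange.
* `dHJ_resolution_CO` / `nicked_HJ_CO` — reciprocal arm exchange at x plus
  hDNA on each non-sister chromatid flanking the junction (same apparent
  direction, non-overlapping: the canonical two-non-sister CO signature).

Optional elaborations, all off in "complications off" mode: template
switches to the sister restore an interior patch of an hDNA tract
(`p_switch`); D-loop migration erases the first-end hDNA at COs, leaving it
transient (`p_dloop_erase`) — this is what produces the dominant
single-chromatid CO transfer class; double-strand gap repair writes a
central full-conversion tract (`p_gap`); HJ branch migration writes short
symmetric hDNA on both chromatids (aberrant 4:4*, `p_branch_migration`,
width 260 bp — the average inter-junction distance of visualised dHJs);
nick translation can place the second CO tract on the far side of the
junction, flipping its apparent direction (`p_invert`, default 0, frequency
unknown); intersister repair thins interhomolog events (`p_sister`);
mitotic 4:0 artifacts can be injected to exercise the filter
(`mitotic_rate`).

After repair, the first mitotic division separates each chromatid's strands
into mother and daughter cells (octad). In wild-type mode `apply_mmr`
converts each hDNA tract toward the donor with probability `p_conv` or
restores it, transient tracts included, then emits four-spore genotypes.

A subtlety the truth log must track: after an earlier crossover, a
"non-sister" donor can be locally identical in sequence to the broken
chromatid, making a later repair genetically silent. Truth tracts therefore
record *informative* markers (donor allele ≠ recipient allele) and CO events
record whether their junction is phase-informative; recovery statistics are
computed against informative events only, and a silent-junction CO is
expected to surface as a NCO if at all.

### Parameter provenance

| parameter | default | rationale |
|-----------|---------|-----------|
| marker spacing | 194 bp | the hybrid's mean polymorphism density |
| DSB mean | 160 / meiosis | physical DSB estimates (140–170) |
| pathway mix | 0.21 / 0.05 / 0.12 / 0.10 / 0.42 / 0.10 | proportional to the observed event inventory: 181 COs (resolution + nicked-HJ) and 169 NCOs split 75 SDSA-like / 59 trans / 35 other over two meioses |
| transfer medians | NCO 1.0 kb, CO 1.6 kb (msh2Δ); 1.8 kb (wild type) | observed median strand-transfer sizes per mode |
| length distribution | log-normal, shape 0.6 | only medians are reported; a positive right-skewed family matches the observed excess of short events, and the shape parameter is an explicit knob |
| `p_nick` | 0.45 | 22 of 50 simple-vs-patched trans events carry a central patch |
| `p_switch` | 0.1 | observed template-switch frequency ("about 10%") |
| `p_dloop_erase` | 0.75 | 119 of 155 transfer-bearing COs affect one chromatid |
| `p_conv` | 0.5 | no-MMR-bias assumption (as many conversions as restorations) |
| `p_asymmetric` / ratio | 0.7 / 3 | 13 of 19 DSBR-compatible COs are clearly asymmetric |
| DSB exclusion | 10 kb per chromatid | keeps same-chromatid tracts from stacking; cross-chromatid proximity is left in deliberately, since real events do co-occur within the 5 kb merge window |

These values were chosen once from the observed inventories and are not
tuning knobs for the test-suite.

### What the generator does and does not emulate

It emulates: two homogeneously diverged parental haplotypes at realistic
marker density; Poisson DSBs placed uniformly, chromosome-weighted by size;
strand-resolved repair by the six pathways with the written states above;
first-mitosis strand separation; MMR conversion/restoration including
transient-tract conversion. It does **not** emulate: marker-density
heterogeneity (Ty-containing deserts), hybridization noise or miscalls
(calls are error-free), crossover interference and homeostasis (DSB
placements are independent), chromatid interference, recombination hotspot
structure, or heterozygosity artifacts of whole-colony genotyping. Passing
tests therefore demonstrate the correctness of the calling logic under the
stated densities, not robustness to array-level noise or to non-uniform
event spacing.

## Statistics

The rank-sum test enumerates the exact mid-rank null distribution over all
C(n, n_a) group assignments when the smaller sample has ≤ 8 observations
(mid-ranks make the enumeration valid under ties); larger samples use the
normal approximation with tie correction. The two-sided p-value is the
null probability of a rank sum at least as far from its null mean as
observed (with a 1e-12 guard against floating-point boundary effects).
The chromosome-size regression is ordinary least squares; R² is the squared
Pearson correlation and its p-value the correlation t-test; constant counts
return R² = 0 with p = 1 rather than the indeterminate 0/0. Report
percentages are rounded half-up to integers to match printed presentation;
raw fractions are retained.

## Problem sizes used by the test-suite

Simulation-backed tests run on scaled-down genomes that keep the study's
*densities* fixed — 1 marker per 194 bp and ~13 DSBs per Mb — while
shrinking total size: recovery uses four 800 kb chromosomes and 40 expected
DSBs over 50 seeds (≈ 1 400 informative events); the segregation oracle
uses two 200 kb chromosomes over 50 seeds (> 50 000 markers compared
exhaustively); the midpoint-length bound checks > 1 000 events. These sizes
are the package's own trade-off between statistical resolution and a test
run measured in seconds; nothing in the logic depends on genome size.

## Known limitations

* Converted-chromatid attribution inside CO events compares against both
  flanking phases; a conversion on an exchanged chromatid that happens to
  match the opposite arm's parent is attributed to the exchange, not the
  conversion — the same ambiguity manual curation faces.
* The merge rule's exception is implemented exactly as stated (conversion on
  a chromatid uninvolved in a *CO*); NCO–NCO pairs on disjoint chromatids
  within 5 kb are still merged, as the stated rules imply.
* `expected_tokens` (the truth-derived oracle) assumes non-overlapping
  events and is used under the per-chromatid exclusion distance; rare
  cross-chromatid overlaps are excluded from the exhaustive comparison.
* Octads are processed natively as eight strands; the historical workaround
  of splitting each octad into two arbitrary tetrads is not reimplemented.
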