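# hdna

Crossover (CO), non-crossover (NCO) and heteroduplex-DNA (hDNA) calling from
octad and tetrad marker genotypes of a polymorphic *Saccharomyces cerevisiae*
hybrid, plus a strand-resolution meiosis simulator for validating the caller
against known ground truth.

## The scientific problem

Meiotic DNA double-strand breaks (DSBs) are repaired off a homologous
chromatid, producing either a crossover — a reciprocal exchange of chromosome
arms — or a non-crossover, detectable only through the gene conversion it
leaves behind. The repair intermediates carry heteroduplex DNA: duplex
regions whose two strands derive from different parents. In a mismatch-repair
deficient (*msh2*Δ) hybrid these heteroduplexes persist into the spores, and
separating each spore's first mitotic division into mother and daughter cell
populations gives the genotype of *all eight DNA strands* of the four
chromatids (an **octad**). At each polymorphic marker between the two parents
(S288C, call value 1; SK1, call value 0) the strand ratio classifies the
marker:

| ratio  | meaning |
|--------|---------|
| 4:4    | Mendelian segregation (parental) |
| 5:3 / 3:5 | half conversion — one heteroduplex chromatid (unrepaired hDNA) |
| 6:2 / 2:6 | full conversion — one chromatid fully converted |
| 4:4\*  | aberrant 4:4 — two heteroduplex chromatids with opposite minorities (symmetric hDNA from Holliday-junction branch migration) |

A pattern of successive segregation tracts, e.g. `3:5_4:4_3:5*`, is the
fingerprint of the repair pathway that produced the event: simple
synthesis-dependent strand annealing (SDSA) leaves one half-conversion tract
on one chromatid; double SDSA and double-Holliday-junction (dHJ) dissolution
leave two adjacent half conversions with the same asymmetry but different
strand distributions (*trans* hDNA, `5:3_5:3*`); dHJ resolution leaves
transfers on both recombining non-sister chromatids. The package implements
the full analysis: segregation calling, tract segmentation, phase-change CO
detection, event merging (< 5 kb, same DSB), midpoint tract-length
estimation, mechanistic classification, and the associated summary
statistics — together with a simulator that writes these strand transfers at
the level of individual strands and logs the ground truth.

## Worked example

Simulate one *msh2*Δ meiosis on a scaled-down genome (four 800 kb
chromosomes, 40 expected DSBs, 1 marker per 194 bp), call events, classify:

```sh
$ printf 'chromosome_sizes: [800000, 800000, 800000, 800000]\ndsb_mean: 40\n' > cfg.yaml
$ hdna simulate --seed 11 --config cfg.yaml --out-prefix demo
simulated 38 DSB events over 16610 markers
$ hdna call demo.genotypes.tsv --out demo.events.tsv
called 14 COs and 12 NCOs -> demo.events.tsv
$ hdna classify demo.events.tsv --out demo.classified.tsv
$ head -7 demo.classified.tsv
chrom   start     end       kind  pattern   chromatid_summary  length_bp  marker_support  class
chr01   92338.0   92513.0   CO    5:3       single             702.0      3               single_chromatid
chr01   136158.5  136158.5  CO    none      none               0.0        0               no_transfer
chr01   223596.0  225677.0  CO    3:5       single             2525.0     19              single_chromatid
chr01   442556.0  442849.0  NCO   3:5_5:3   two-non-sister     627.5      5               other
chr01   482006.0  484194.0  NCO   3:5_3:5*  single             2475.0     15              trans_canonical
chr01   581304.0  582433.0  CO    5:3       single             1278.0     9               single_chromatid
```

Reading the output: the event at chr01:482 kb is a canonical *trans* hDNA —
two adjacent 5:3 tracts on the same chromatid with different strand
distributions, the signature of dHJ dissolution or double SDSA. The event at
442 kb carries half conversions of *both* asymmetry directions on two
non-sister chromatids (dHJ resolution without arm exchange) and lands in the
"other" class. `length_bp` is the midpoint estimate: from the midpoint of
the interval between the last flanking Mendelian marker and the first
converted marker, to the symmetric midpoint on the right. Not every truth
DSB is recoverable — 38 were simulated, 26 called — because short tracts can
cover fewer than two markers (the single-marker discard rule) and events
closer than 5 kb are combined.

The fixture-derived headline numbers of the pattern inventories ship with
the package and can be recomputed at any time:

```sh
$ hdna reproduce-tables
msh2_co_multitract_percent       43
wt_co_multitract_percent         5
msh2_nco_single_half_conversion  66
msh2_nco_canonical_trans         28
msh2_nco_trans_with_patch        22
msh2_nco_opposite_directions     4
```

## Package layout

| module | role |
|--------|------|
| `hdna.io` | genotype-table dialect (read/write), pattern-inventory fixtures |
| `hdna.patterns` | ratio-token grammar, canonicalization, NCO/CO classification |
| `hdna.segregation` | per-marker segregation calls, signature-run tract segmentation |
| `hdna.events` | phase inference, CO/NCO calling, 5 kb merging, midpoint lengths |
| `hdna.simulate` | strand-resolution meiosis simulator with truth log, MMR model |
| `hdna.stats` | class fractions, rank-sum tests, size regression, length medians |
| `hdna.evaluate` | truth-vs-called matching, truth-derived segregation oracle |
| `hdna.cli` | `hdna simulate / call / classify / report / reproduce-tables` |

See `docs/methods.md` for the model, parameter provenance and known
limitations.
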