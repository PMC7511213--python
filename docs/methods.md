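# Methods

## The editing model

A cytosine base editor (CBE) is modelled by five targeting parameters: an
IUPAC PAM pattern (e.g. `NGG`, `NG`, `NNGRRT`, `TTTV`, `NGCG`), the side of
the protospacer the PAM sits on (3' for Cas9-family editors, 5' for
Cas12a), the spacer length, and an editing window `[window_start,
window_end]`. Window positions are counted 1-based from the 5' end of the
protospacer written 5'→3' on its own strand; this is the convention under
which YEE-BE3's sole editable base is "position 6", and it is applied
uniformly to both PAM sides. Biochemistry is abstracted to a single rule:
any C on the protospacer strand inside the window may be converted to T.

The registry ships 13 presets. Parameters beyond the PAM patterns that are
fixed by each editor's Cas domain are taken from the primary
characterization papers (Komor et al. 2016 for BE3; Kim et al. 2017 for
the Sa, VQR/VRER and narrowed-window YE1/EE/YEE variants; Hu et al. 2018
for xCas9; Jiang et al. 2018 for BE-PLUS; Nishida et al. 2016 and
Nishimasu et al. 2018 for Target-AID(-NG); Li et al. 2018 for the dCas12a
editor). Local-context activity preference is a per-model ranked list
defaulting to TC > CC > AC > GC; it annotates sites but never filters
them.

## Spacer search

For a CDS of length `3n` codons the search enumerates every placement `p`
of the protospacer on both strands for which protospacer and adjacent PAM
lie fully inside the CDS and the PAM matches. For a qualifying placement,
every editable base in the window (sense C for a plus-strand spacer; sense
G — i.e. antisense C — for a minus-strand spacer) is mapped to its codon.
A codon qualifies when some nonempty subset of its in-window editable
positions, converted C→T on the protospacer strand, turns it into a stop
codon of the active genetic code that is not the natural terminator. The
implementation simulates the edit and re-translates rather than matching a
codon list, so non-standard genetic codes work unchanged; that the
standard-code answer is exactly {CAA, CAG, CGA, TGG} is a verified,
emergent property (the test suite proves it by exhaustive scan of all 64
codons, and derives the different set for the ciliate code the same way).

Reporting choices, made where several readings were defensible:

* one row per (placement, edited codon) — a placement able to disrupt two
  codons yields two rows, since downstream filtering is per codon/context;
* `edit_positions` records the *minimal* stop-creating subset (fewest
  edited bases, ties broken toward the 5' end of the protospacer);
  bystander edits do not affect qualification;
* a codon straddling the window edge qualifies only if the stop-creating C
  itself is inside the window;
* the search-region filter ("top N% of the CDS body", default 50%,
  batch grid 25/50/75%) is anchored on the first base of the *edited
  codon*: the premature stop's position is what determines truncation
  severity, so it, rather than the spacer or PAM, decides region
  membership;
* an edit recreating a stop at the final codon is not premature and is
  never reported; sites whose protospacer or PAM contains N are skipped
  silently; a CDS with length not divisible by 3 is processed with a
  warning, ignoring the trailing bases.

The context annotation is the base 5' of the 5'-most stop-creating C *on
the edited strand* (for minus-strand spacers this is the complement of the
plus-strand base 3' of the edited position). A stop-creating C at the very
first base of the CDS has no 5' neighbour and is reported with context
`NC`, unranked.

## ORF detection

ORFs are maximal start→stop runs on each of the six frames: the 5'-most
qualifying start per (frame, stop), no internal stop, length (including
the stop codon) at least `min_len` (default 75 nt; the interactive range
is 24–150 nt and is enforced in strict mode only). Runs without a
terminating stop are not reported — the inactivation use-case needs a
bounded CDS. Codons containing N never match start or stop codons. In
batch mode each input record is assumed to *be* a CDS: frame +1 is
validated (start codon, terminal stop, no internal stop, length divisible
by 3) and violations are warnings, not errors, because silently dropping
records would change the denominator of every downstream ability ratio.

## Off-target search

The anchor algorithm splits the spacer into `m + 1` contiguous fragments
whose lengths differ by at most one. Any genomic window within Hamming
distance `m` of the spacer agrees with it on all but at most `m`
positions, and `m` mismatches can touch at most `m` of the `m + 1`
fragments, so at least one fragment occurs exactly — exact fragment
occurrences (found by plain substring scanning on both strands) are
therefore a complete candidate set. Each candidate window is verified by
(a) an exact IUPAC match of the adjacent PAM on the side the editor
requires and (b) total Hamming distance ≤ `m` over the full spacer.
Mismatch counting is substitution-only; indels are out of scope. A
genomic N counts as a mismatch and never satisfies a PAM letter. The
budget is inclusive (`≤ m`), so `m = 0` finds exact matches. Seed-region
weighting is deliberately not applied as a filter: the mismatch count and
site sequence are reported so users can impose their own seed rules.

Contigs are streamed in tiling segments (default 50 Mb) plus, for every
internal tile boundary, a junction segment of twice the flank (default
100 nt) centred on the boundary. Hits are deduplicated on
(spacer, contig, start, strand), which collapses both multi-anchor
discoveries and tile/junction duplicates; windows running past a contig
end are skipped. The tests shrink `segment_size` to 1 kb to exercise the
boundary logic at desk scale; the defaults are configurable
(`--segment-size`, `--flank`).

## Batch evaluation

`run_batch` computes whole-CDS site sets once per (CDS, editor) and
derives all per-region tables and abilities from those same site sets, so
the counts can never drift apart. The ability of an editor at region
fraction *f* is `|{CDS with ≥1 site at cds_fraction ≤ f}| / n_CDS`; it is
non-decreasing in *f* by construction, and an editor whose editing window
is a superset of another's (same PAM, same spacer) dominates it pointwise
— both properties are asserted in the suite. Invalid CDSs stay in the
denominator (with a logged warning). Tables are deterministic given
inputs; plots are optional side outputs so headless runs assert on tables
only.

## Synthetic data

The fixtures generator is the package's test substrate and defines the
conditions the suite measures under. CDS sets are i.i.d. codon sequences
at a target GC (default 0.5; evaluation runs in the acceptance script use
0.44, a typical bacterial coding GC), length range 300–1800 nt by default
(desk-scale; bacterial CDSs average ~1 kb), with a valid start, a single
terminal stop and no internal stop. Planted features are engineered
directly: an editable codon is written at a codon index within the
requested region fraction, with a concrete PAM expansion placed so the
editing window covers the edited base, and repaired so no internal stop
appears; the expected detection outcome is recorded in a ground-truth
ledger next to the sequences. Genomes are i.i.d. backgrounds with spacer
copies planted at exact Hamming distances and valid or deliberately
invalid PAMs; after assembly the genome is self-scanned with a naive
full-window Hamming oracle and redrawn if the background happens to
contain an unplanned near-match, making expected hit counts exact. What
the generator does *not* emulate: repeats, codon-usage bias, isochores,
real PAM density correlations — so passing tests demonstrate algorithmic
correctness and the direction of compositional effects (e.g. T-rich PAMs
are commoner in AT-rich sequence), not species-level ability values,
which depend on a real CDS FASTA supplied by the user.

## Numerical and scale choices

Everything is exact integer/string computation; there are no tolerances
to tune. Oracle-equivalence suites run at sizes chosen to finish quickly
while covering every code path: 50+ random CDSs of 0.3–3 kb across four
presets for the design search, 20 planted genomes of 20–100 kb at
mismatch budgets 0–3 with 1-kb segmentation for the off-target search,
and 20 random 10–50 kb sequences for ORF detection. The acceptance script
uses a 120-CDS set and a 100-kb genome for the same reason. Determinism:
every random draw flows from an explicit seed; hypothesis profiles are
derandomised.

## Known limitations

* No editing-efficiency prediction beyond context rank; no seed-region
  off-target scoring.
* Substitution-only off-target model; bulge/indel off-targets are
  invisible to it.
* Alternative (non-5'-most) start codons of an ORF are not enumerated.
* The off-target scan is a streaming string search, not an FM-index; it
  favours zero preprocessing and bounded memory over repeated-query
  speed.
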