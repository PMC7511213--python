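# cbei

Design and evaluation of sgRNA spacers for **cytosine base editor-mediated
gene inactivation** (CBEI).

Cytosine base editors (CBEs) — fusions of a Cas nickase/dead Cas, a cytidine
deaminase and usually a uracil glycosylase inhibitor — convert C•G to T•A
within a short *editing window* of the protospacer, without a double-strand
break. Applied inside a coding sequence, this chemistry can create a
premature stop codon: under the standard genetic code, sense-strand editing
converts CAA→TAA, CAG→TAG and CGA→TGA, and antisense-strand editing converts
TGG→TAG/TGA/TAA. A gene disrupted this way acquires a truncating nonsense
allele, which makes CBEs a practical knockout tool in recombination- and
NHEJ-deficient organisms.

`cbei` is for researchers building such knockouts or whole
gene-inactivation libraries. It

* detects ORFs on all six frames (25 NCBI genetic codes) to locate the
  target CDS;
* finds every spacer for a given editor whose in-window C→T edit creates a
  premature stop, with the 5'-dinucleotide activity context
  (TC ≥ CC ≥ AC > GC) and a configurable 5' search region;
* screens spacers against arbitrary genome FASTA for off-target sites using
  a pigeonhole *anchor* search: the spacer is split into *m*+1 contiguous
  exact fragments, so any locus within Hamming distance *m* must contain one
  fragment verbatim; exact fragment hits are then verified by PAM adjacency
  and full-spacer mismatch count. Large genomes are streamed in 50-Mb
  segments plus short boundary-spanning junction segments;
* batch-evaluates editors on a CDS set: the **inactivation ability** of an
  editor at search region *N*% is the fraction of CDSs with at least one
  qualifying site whose premature stop falls within the first *N*% of the
  CDS body.

Thirteen editor presets are built in (BE3, xBE3, BE-PLUS, SaBE3,
Sa(KKH)-BE3, VQR-BE3, VRER-BE3, YE1-BE3, EE-BE3, YEE-BE3, Target-AID,
Target-AID-NG, Cas12a-BE); custom editors (PAM pattern/side, spacer length,
editing window) are a YAML file away.

## Worked example

Generate a small synthetic CDS set with a planted BE3-editable CAA codon and
design spacers:

```bash
python - <<'EOF'
from cbei.fixtures import FixtureSpec, PlantedSite, make_cds
from cbei.seqcore import write_fasta
recs, ledger = make_cds(FixtureSpec(seed=12, n_cds=2, length_range=(450, 600),
                                    plants=(PlantedSite(cds_index=0, model='BE3'),)))
write_fasta(recs, 'demo.fasta')
EOF
cbei design --in demo.fasta --cbe BE3 --out sites.tsv
```

which prints per-record summaries

```
cds1: 3 sites in whole CDS, 2 in top 50%
cds2: 4 sites in whole CDS, 3 in top 50%
```

and writes one row per (spacer placement, edited codon):

```
cds_id  cbe  strand  proto_start  spacer                pam  window  codon_index  codon_before  codon_after  edit_positions  context  context_rank  cds_fraction  annotation
cds1    BE3  +       117          CATACAACTCTACTCTCCTC  AGG  4-8     41           CAA           TAA          5               AC       3             0.222836      {CAT[A(c>T)AAC]TCTACTCTCCTC}|AGG CAA>TAA@41
cds1    BE3  +       130          TCTCCTCAGGAAAGGCCACT  AGG  4-8     46           CAG           TAG          7               TC       1             0.25046       {TCT[CCT(c>T)A]GGAAAGGCCACT}|AGG CAG>TAG@46
```

Read the first row as: on the sense strand, the 20-nt spacer starting at
CDS base 117 has PAM `AGG`; editing the C at window position 5 turns codon
41 from CAA into the stop TAA, 22% of the way into the CDS (well inside the
default top-50% search region). The annotation shows the spacer in braces,
the editing window in brackets, the stop-creating edit in parentheses and
the PAM after the pipe; `context_rank` 1 (TC) marks the most active local
context, rank 4 (GC) the least.

Screen the designed spacers and evaluate all 13 editors:

```bash
cbei offtarget --spacers sites.tsv --genome genome.fasta --cbe BE3 --mismatch 3 --out hits.tsv
cbei evaluate --in cds_set.fasta --cbe all --regions 25,50,75 --out-dir results/
```

`cbei evaluate` writes one site table per region, `ability.tsv` (editor ×
region ability grid), CDS length/GC statistics with ECDF tables, and
optional ability-curve plots (`--plots`).

## Layout

| module | role |
| --- | --- |
| `cbei.seqcore` | FASTA/plain-text ingest, genetic codes, exon splicing, strand primitives |
| `cbei.orf_finder` | six-frame ORF detection and CDS validation |
| `cbei.cbe_model` | editor presets, custom models, IUPAC PAM matching |
| `cbei.cbei_design` | the stop-creating spacer search |
| `cbei.offtarget` | anchor off-target search with genome segmentation |
| `cbei.evaluate` | batch pipeline, ability curves, CDS-set statistics |
| `cbei.fixtures` | seeded synthetic CDSs/genomes with ground-truth ledgers |
| `cbei.cli` | the `cbei` command line |

See `docs/methods.md` for the model, algorithms, parameter choices and
limitations.
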