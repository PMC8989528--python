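# lesionmux

Analysis pipeline for **multiplexed site-specific DNA-lesion mutagenesis
assays** read out by next-generation sequencing.

In this assay family, a single modified base (here: oxo-ϵA,
7,8-dihydro-8-oxo-1,*N*⁶-ethenoadenine, an adenine-derived thymine mimic) is
placed at a defined coordinate of a single-stranded M13-style phage genome.
The site sits inside a 16-mer *lesion oligo* carrying a trinucleotide
sequence context (5′N‑X‑N3′), which is ligated to an 18-mer *barcode oligo*
whose trinucleotide barcode identifies the construct; the 34-mer ligation
product is spliced into the genome. After replication in *E. coli* strains
that are proficient or deficient in candidate repair pathways, the region
around the insert is sequenced paired-end, and the base found at the lesion
site in progeny reads encodes the mutagenic outcome.

`lesionmux` implements the full computational side of that experiment, with
a seeded simulator standing in for the wet-lab replication step so that
every stage is testable offline:

1. **`lesionmux.constructs`** — construct geometry: oligo validation, pool
   enumeration (e.g. 16 contexts × {A, oxo-ϵA} = 32 constructs), barcode
   tables, construct sheets (TSV).
2. **`lesionmux.simulate`** — paired-end FASTQ simulation from a molar mix
   of constructs with configurable lesion-outcome profiles, substitution
   sequencing error, malformed (truncated-insert) contamination, and a
   truth table for validation.
3. **`lesionmux.extract`** — overlap-consensus read merging, anchored
   extraction of the insert between genomic flanks, the exact-34-nt length
   filter, exact trinucleotide barcode demultiplexing, template
   verification, and a per-read PASS/REJECT ledger that always conserves
   counts.
4. **`lesionmux.spectrum`** — per-position pileups over the region of
   interest (construct coordinates 6244…6280), lesion-site miscoding
   fractions *f*\_A … *f*\_T, mutation frequency 1 − *f*\_ref, and
   depth-weighted pooling across contexts and replicates.
5. **`lesionmux.stats`** — bypass efficiency as the CRAB-style
   lesion:control read-count ratio (ratio 1 at equimolar input = 100%
   bypass) with a seeded bootstrap CI, and one-way ANOVA + Tukey HSD for
   comparisons across genotypes or sequence contexts (α = 0.05).
6. **`lesionmux.pipeline` / `lesionmux.cli`** — end-to-end orchestration
   with a reproducible report (per-stage counts, config hash, recovery
   diagnostics against the simulation truth).

## Core quantities

For a group *g* (lesion × genotype × context × replicate) with lesion-site
base counts *n*\_A, *n*\_C, *n*\_G, *n*\_T and depth *N*:

- miscoding fractions: *f*\_b = *n*\_b / *N*
- mutation frequency: *μ* = 1 − *f*\_A (A is the cognate base)
- mutation-class share among mutants: e.g. A→T share = *f*\_T / (1 − *f*\_A)
- bypass efficiency: (reads\_lesion / reads\_control) / molar ratio × 100%

## Worked example

Run the packaged equimolar TXG design (one adenine control construct and
one oxo-ϵA construct, 20,000 read pairs, substitution error 10⁻³, 2%
malformed inserts):

```sh
lesionmux run --seed 17 --out demo/txg
```

prints

```
lesionmux 0.1.0  sample=sample1
seed=17  config_hash=184dcef9c23fbaf5

read pairs: 20000
  PASS             19550
  REJECT_MERGE     0
  REJECT_TEMPLATE  3
  REJECT_LENGTH    401
  REJECT_BARCODE   46
pooled A: depth=9905 mutation_frequency=0.0031
pooled oxoeA: depth=9645 mutation_frequency=0.9718
bypass: 97.4% [94.8, 100.2]
recovery: misassignments=6
```

Reading this: of 20,000 simulated pairs, 401 carried truncated inserts
caught by the 34-mer length filter and 49 were lost to sequencing errors in
anchors or barcode; the adenine control shows the ~0.3% noise floor while
the oxo-ϵA construct is ~97% mutant (mostly A→T, see
`demo/txg/spectra.tsv`); the lesion:control read ratio estimates ~97%
bypass with a bootstrap CI covering 100%, i.e. no detectable replication
blocking. The ledger (PASS + rejects = input pairs) is enforced on every
run. Full machine-readable output is in `demo/txg/report.json`,
per-construct spectra in `spectra.tsv`, per-position counts in
`pileup.tsv`.

Subcommands `simulate`, `extract`, `spectrum`, `bypass` and `stats` expose
the individual stages; `lesionmux --help` lists options.

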