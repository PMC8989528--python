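# Methods

## The assay being modelled

A single modified base is placed at a known coordinate of a single-stranded
phage genome via a 34-mer insert: an 18-mer barcode oligo (trinucleotide
barcode at positions 8–10) ligated to a 16-mer lesion oligo (interrogated
base at position 8, giving a 5′N‑X‑N3′ trinucleotide context from positions
7–9). The genome replicates in a host; whatever base ends up opposite the
lesion during replication is fixed into progeny genomes, so the base
composition at the lesion coordinate in progeny sequencing reads *is* the
miscoding spectrum of the lesion. A control genome carrying unmodified
adenine at the same site measures the noise floor, and — when lesion and
control genomes are mixed equimolar before transfection — the ratio of
validated reads attributable to each genome estimates the lesion's
replication-bypass efficiency (the read-count version of a competitive
replication of adduct bypass, CRAB, experiment).

## Construct geometry

The package does not ship a phage genome sequence. A 7,000 nt pseudo-random
stub (fixed internal seed, alphabet ACGT) stands in for it, and the insert
is placed so that the lesion falls at assembled-construct coordinate 6262 —
the centre of the 6244…6280 region of interest over which pileups are
computed. This keeps the coordinate system of real experiments of this type
meaningful while requiring no download. All coordinates are 1-based
inclusive.

Oligo scaffolds are fixed sequences with the variable trinucleotide
(barcode, or context with central placeholder `X`) spliced in. Barcode
sequences are a bookkeeping choice; the default assignment walks
trinucleotides in lexicographic order, and any assignment can be supplied
via the construct sheet. Within a pool every (barcode, context) pair is
unique and duplicate barcodes are a hard error.

## The generative read model

`simulate_reads` emulates the post-replication sequencing library:

| parameter | default | meaning / rationale |
|---|---|---|
| `n_read_pairs` | per design | sample depth |
| `read_length` | 150 nt | typical desktop-sequencer paired-end length |
| `fragment_length` | 240 nt | amplicon window centred on the insert; must be ≤ 2×read length − overlap so pairs merge (240 → 60 nt overlap) |
| `substitution_error_rate` | 0.001 | i.i.d. per-base substitution to one of the three other bases; order of magnitude of post-filter short-read error |
| `malformed_insert_fraction` | 0.02 | fragments carrying a truncated insert (uniform 28–33 nt), modelling failed ligation products; exercises the 34-mer filter |
| `quality_phred` | 30 | constant quality; the pipeline uses quality only for overlap tie-breaking |
| `seed` | 17 | one integer; multi-sample experiments derive per-sample child streams via `numpy.random.SeedSequence` |

Each fragment draws its construct of origin from the molar fractions of the
genome mix (multinomial sampling — an equimolar mix therefore shows
binomial counting noise, exactly as a sequencer sampling a balanced library
does), then draws its lesion-site base from the construct's **outcome
profile** (p_A, p_C, p_G, p_T summing to 1). R1 is the fragment 5′ end, R2
the reverse complement of its 3′ end, Phred+33. A truth table
(fragment → construct, lesion base, malformed flag) accompanies every run.

### Outcome presets

These are the generative ground truth the pipeline is asked to recover, set
to the outcome levels characteristic of oxo-ϵA replication in *E. coli*:

- `control_A`: 99.8% A, remaining 0.2% split evenly — the assay noise
  floor; chosen below all effect sizes of interest.
- `oxoeA_TXG`: 97% mutant with 95% of mutations A→T
  (p = 0.03/0.02425/0.02425/0.9215 for A/C/G/T); the C/G remainder is split
  symmetrically, a choice, since only the mutant total and the A→T share
  are constrained.
- `oxoeA_pool_default` (13 contexts): p = 0.005/0.006/0.006/0.983 — >99%
  mutant, nearly all A→T.
- `oxoeA_pool_GXC_GXG_GXT`: p = 0.005/0.02/0.003/0.972 — the three
  5′G contexts where ~2% of reads carry C at the lesion site (consistent
  with occasional lesion:G pairing).

Mixing the 16 pool presets at equal depth gives a pooled A→T share among
mutants of (13·0.983 + 3·0.972)/(16·0.995) ≈ 0.986 — the closed-form value
the aggregation tests pin.

## Extraction and filtering

- **Merging**: largest 3′(R1)/5′(R2) overlap with mismatch fraction ≤ 0.1
  and length ≥ 10 is accepted; discordant overlap bases resolve to the
  higher-quality read, ties to R1. The merge procedure is a reconstruction
  of generic overlap-consensus concatenation, not a reimplementation of any
  specific tool. At constant simulated quality the tie rule means R1's
  errors are the ones that survive merging.
- **Anchoring**: the 20 nt genomic flanks abutting the insert are located
  by gapless best-placement search (≤ 2 mismatches each); the between-anchor
  subsequence must be exactly 34 nt (`REJECT_LENGTH` otherwise,
  `REJECT_TEMPLATE` if an anchor cannot be placed). A general-purpose
  aligner is deliberately not used: the construct is known, and anchored
  extraction is exact and auditable.
- **Demultiplexing**: the barcode trinucleotide must match the table
  *exactly* — lexicographically assigned trinucleotide barcodes sit at
  Hamming distance 1, so 1-mismatch rescue would create cross-talk;
  rejection is safer. The 16-mer is then verified against its template
  tolerating ≤ 1 mismatch outside the lesion position, which retains
  sequencing-error reads while excluding chimeras.
- **Ledger**: every input pair yields exactly one PASS or REJECT row;
  Σ categories = input pairs is asserted at the pipeline level.

A consequence of exact barcode matching worth knowing: at nonzero
sequencing error a barcode base-call error can convert one valid barcode
into another, producing rare misassignments (~10⁻⁴ per read at the default
error rate). With error rate 0 misassignments are exactly zero, which the
truth-table tests enforce.

## Spectrum

Pileups count insert bases only (the 34-mer clipped to the region of
interest); ROI positions outside the insert have zero depth. The lesion-site
miscoding result reports fractions on two scales — per-mutant-read shares
(f_T/(1 − f_A)) and all-read fractions (f_T) — because context-resolved
figures in this assay family are conventionally drawn on the all-reads
scale while "X% of mutations are A→T" statements use the mutant-read scale.
The lesion→C outcome in the GXC/GXG/GXT contexts is reported as an
all-reads fraction. No sequencing-error correction is applied; the control
construct is the empirical noise floor. Pooling sums raw counts
(depth-weighted), making it associative and order-independent; pooling a
lesion with its control is refused unless explicitly overridden. Zero depth
yields a flagged no-coverage result rather than an error.

Technical PCR triplicates are treated as pooled before analysis; the
replicate dimension of the statistics refers to biological replicates.

## Statistics

- **Bypass**: ratio of validated lesion to control reads, normalised by
  the input molar ratio; 1.0 ⇔ 100% bypass. Uncertainty via a seeded
  binomial bootstrap (10,000 resamples of the reads' construct of origin),
  percentile CI, level configurable (default 95%). The wet-lab ratio has no
  published uncertainty; the bootstrap makes "no significant difference"
  an assertable output (`equal_coverage_test` gives the two-proportion z
  test against the input ratio).
- **ANOVA + Tukey**: one-way fixed-effects ANOVA computed from the
  definitional between/within sums of squares (so it is directly checkable
  against brute-force computation), Tukey HSD via the studentized range
  distribution with the Tukey–Kramer standard error for unequal group
  sizes, family-wise α = 0.05. With two groups the Tukey adjusted p equals
  the ANOVA p (q = √(2F) identity). Responses are untransformed replicate
  mutation frequencies — no arcsine/logit transform is applied, and values
  near 0/1 should be interpreted with that in mind. Zero within-group
  variance reports an infinite F with an exact-tie warning; a group with a
  single replicate is an error naming the group.

## Numerical and design notes

- Probabilities are validated to sum to 1 within 1e-12; outcome profiles
  are stored as exact floats (e.g. the control off-target mass is 0.002/3
  per base, not a rounded decimal).
- Lesion-site sampling uses inverse-CDF draws from one `default_rng`
  stream; identical configurations are byte-identical in FASTQ and truth
  output.
- Overlap search scans from the largest possible overlap downward and
  accepts the first admissible one; for uniform read lengths the pipeline
  uses a vectorised batch equivalent verified to match the per-pair
  routine exactly.
- Anchor search ties break leftmost; the right anchor is constrained to lie
  after the left one.
- Problem sizes used by the packaged checks — 50,000 pairs for the
  single-context recovery, 32 × 3,000 pairs for the 16-context pool,
  50,000 pairs for the bypass mix, 10,000 bootstrap resamples, 1,000
  Monte-Carlo families for the Tukey calibration — give recovery standard
  errors of ~0.1 percentage points at the lesion site, comfortably below
  every effect of interest, while keeping a full run on one CPU in tens of
  seconds.

## What the simulation does and does not show

The generator reproduces the *outcome statistics* of the assay: miscoding
proportions per context, filterable ligation failures, read-sampling noise
and i.i.d. substitution errors. It deliberately does not model PCR
amplification bias, indels, quality-score variation along reads, Illumina
indexing chemistry, chimera formation, strand bias (the input genome is
single-stranded), or phage-replication kinetics. Passing recovery tests
therefore demonstrates that the pipeline's filtering, demultiplexing and
estimation are correct and unbiased under realistic counting noise — not
that real libraries are free of the artefacts listed above. The malformed
class is a stand-in for failed ligation; how residual unligated or
re-circularised genomes actually behave in a real sequencing run is outside
what the truncation model claims.
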