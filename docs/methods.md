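# Methods

This note documents the models, parameter choices and numerical conventions
behind `allelescreen`, and what the simulator-based tests do and do not
demonstrate about real libraries.

## Assay model

A screening panel consists of SNPs rendered as 21-nt double-stranded oligo
templates, one per allele, with the polymorphic base at the 11th (central)
position and 10 nt of fixed genomic flank on each side.  All templates of
one SNP therefore differ pairwise at exactly one position.  In the
protein-binding assay (SNPs-seq) an equimolar template pool is incubated
with nuclear extract; protein-bound oligos are retained on a purification
column and sequenced (50-bp single-end), so per-allele read counts report
allele-dependent binding.  In the enhancer assay (targeted STARR-seq) the
candidate regions are cloned as ~600-bp amplicons into a self-transcribing
reporter; 100–150-bp sheared fragments are sequenced (100-bp paired-end)
from mRNA and from the transfected plasmid pool.

Both assays are quantified by the same statistic, a log2 double ratio of
variant/reference read counts in a test sample versus its matched input:

    score = log2[(RC_var/RC_ref)_test] − log2[(RC_var/RC_ref)_input]

The input ratio cancels allele-specific pooling, synthesis and cloning
imbalances, so the score isolates the binding (BAB) or enhancer (BAE)
effect.  A score of ±0.58 corresponds to a 1.5-fold allelic difference and
is the default significance cutoff; when eQTL P values are supplied as
annotations, significance additionally requires P ≤ 1e−5.  Both cutoffs are
inclusive and configurable.

## Panel design and thermodynamic QC

Read counts in pooled-oligo libraries depend strongly on oligo composition:
low-GC and weakly pairing oligos anneal inefficiently into duplexes and are
under-represented.  Each template is therefore annotated with:

* **GC fraction** (Biopython's `gc_fraction`).
* **Melting temperature** — two-state nearest-neighbor model with the
  SantaLucia (1998) unified ΔH/ΔS parameters, embedded in
  `allelescreen.thermo` under the version tag `santalucia-1998-unified`.
  Tm = ΔH·1000/(ΔS + R·ln(CT/4)) − 273.15 for non-self-complementary
  duplexes with equimolar strands (odd-length templates cannot be
  self-complementary), with the SantaLucia entropic salt correction
  0.368·(N−1)·ln[Na+].  Defaults: 50 mM Na+ and CT = 5.05 nM, the pooled
  per-oligo concentration of the intended use case; both are overridable.
* **Duplex ΔG°37** — ΔH − 310.15·ΔS/1000, reported at the 1 M NaCl reference
  state where these tables are defined.  More negative = more stable.
* **Terminal classes** — 5′/3′ mono- and dinucleotides; terminal AA/AT/TA/TT
  are empirically the lowest-yield classes.

`flag_low_yield` summarizes these into LOW_GC (GC < 0.25 by default),
AT_END5/AT_END3 (terminal dinucleotide in {AA, AT, TA, TT}) and WEAK_DUPLEX.
The WEAK_DUPLEX threshold (ΔG°37 > −20 kcal/mol) is this package's own
choice: for 21-mers it sits near the boundary between the AT-rich tail and
the bulk of the distribution.  Panel-level QC also reports the expected
library fragment size (insert + 140 bp of adaptors, i.e. 161 bp for a 21-bp
insert) and per-oligo amounts from pool mass arithmetic
(mass/n/(length·660 g/mol/bp)).

Genomic coordinates are 1-based in all I/O (VCF convention); within-oligo
offsets are reported 1-based ("11th nucleotide") and handled 0-based
half-open internally.  IUPAC ambiguity codes are rejected outright — the
assay depends on exact sequences, so silently skipping them would corrupt
panels.

## Perfect-match counting

Reads are assigned by exact full-template substring occurrence, either
strand, with no quality filtering.  This reflects the library structure —
a 21-nt insert embedded in adaptor sequence within a 50-bp read — and avoids
any dependence on adapter trimming.  The index holds every template sequence
and its reverse complement and fails loudly on collisions (including
cross-strand ones), since a collision would make counts ambiguous.

Ambiguity policy: a read containing full templates of two or more distinct
SNPs is tallied as ambiguous and excluded (the default, appropriate for
SNPs-seq where one read carries one insert).  Long STARR-seq reads
legitimately span several clustered SNPs, so counting also offers a
`count_each` mode crediting every covered SNP once; a read or read pair
supporting two alleles of one SNP is always excluded.  Paired-end data are
counted per read, not per pair, with the pair used only for the conflict
check.  Accounting is conservative in every mode:
assigned + ambiguous + off-target = total.

QC statistics include the on-target fraction (assigned/total), per-template
depth summaries, replicate concordance (Pearson R² of log2(count + 1)) and
a composition-bias report (R² of log2 counts against GC/Tm/ΔG, grouped
quartiles by terminal class).  Replicate concordance on zero-variance tables
is refused explicitly rather than returned as a silent NaN.

## Scoring conventions

* The score is computed as (log2 t_var + log2 i_ref) − (log2 t_ref +
  log2 i_var), a grouping that makes the variant/reference swap negate the
  result bit-exactly.
* Zero handling: if any of the four counts is zero, a pseudocount (default
  1) is added to **all four** and the result is flagged `pseudocounted`;
  this keeps scores finite while preserving antisymmetry.  All four zero
  yields NaN, reported as missing.
* Technical replicates are pooled by summing counts — the maximum-likelihood
  treatment of multinomial sampling — with per-replicate scores retained for
  dispersion QC.
* Hormone-treated (DHT) and vehicle (ETH) conditions are scored separately
  and never mixed; SNP selection accepts a qualifying score in either
  condition, and any qualifying variant allele selects its SNP.
* Summary outputs round scores to two decimals; machine-readable TSVs carry
  full precision.

## Enhancer analysis

STARR-seq allele counts are normalized to reads per million assigned
template observations (RPM), which makes the normalized values sum to 1e6
per sample by construction.  SNPs enter BAE scoring only if at least one
allele differs ≥ 1.5-fold between test and input RPM.  The filter is
two-sided by default (a "difference" can be enrichment or depletion,
i.e. enhancer- or silencer-like), with a one-sided switch; the threshold is
inclusive.  A pseudocount of 1 RPM on both sides keeps zero-input alleles
finite — the choice is ours and matters only for alleles near zero depth.

### Haplotype-resolved scoring

For SNP clusters small enough to be covered by one read, haplotypes are read
directly off spanning reads: a read contributes if and only if it exactly
matches a window of one allele-substituted amplicon variant (mismatches are
allowed only at declared SNP offsets, via the substitution) and the window
covers every SNP of the cluster.  Reads spanning a strict subset of the
SNPs are excluded entirely rather than partially phased.  Haplotypes outside
the declared set are tallied separately as `other`.  The haplotype BAE
applies the standard score to a chosen variant/reference haplotype pair per
amplicon; the cross-amplicon summary is the unweighted mean and min–max
range, with per-amplicon depths available for weighted reanalysis.

## Simulator

The simulator provides ground truth for parameter-recovery tests.

**SNPs-seq.**  Input samples draw templates near-uniformly (an optional
exponential GC-yield bias is available but off by default); test samples
multiply each variant template's weight by its true binding ratio r, so the
expected score is exactly log2 r.  A configurable fraction of reads is
uniform-random "naked DNA" background — defaults 0.40 for test samples and
0.05 for input controls, reproducing the observed on-target regimes of
roughly 60% and 95% — and uniform per-base substitution errors (default
0.001, typical of Illumina short reads) push reads off-target under the
perfect-match rule.  Reads are 50 bp with the 21-nt template at a uniform
random offset and random flanking bases standing in for adaptor context.

**STARR-seq.**  Plasmid samples draw (amplicon, haplotype) units by the
declared haplotype frequencies; mRNA samples multiply those weights by the
haplotype's enhancer activity, so the expected haplotype BAE is
log2(activity_var/activity_ref) independent of the pool composition.
Fragments are sheared uniformly: length uniform on 100–150 bp, start uniform
over the amplicon; mates are the first 100 bp of each fragment end.
Background fraction defaults to 0.2 (observed mapped fractions ~70–81%).

All randomness derives from a single integer seed through numpy's PCG64
generator; the algorithm identity is recorded in outputs so summary
statistics are reproducible across reimplementations (byte-identical FASTQ
is promised only within this implementation).  Quality strings are constant
placeholders because counting ignores quality.

**What the simulator does not model:** PCR duplicates and amplification
jackpots, indels and adapter read-through, position- or motif-dependent
error profiles, genomic (non-uniform) background sequence, GC-dependent
yield bias by default, and cross-replicate overdispersion beyond multinomial
sampling.  Passing recovery tests therefore demonstrates correctness of the
counting and scoring machinery under the declared sampling model, not
robustness to every artifact of real libraries.

## Test problem sizes

Parameter recovery uses binding ratios r ∈ {0.25, 0.5, 1, 2, 4} on a 5-SNP
panel at 100,000 reads per sample across 20 seeds, asserting the mean score
within three delta-method standard errors of log2 r (the delta-method
variance of the score is (1/ln 2)²·Σ 1/count), and |mean| < 0.05 for the
null.  The haplotype recovery run uses three staggered 600-bp amplicons
sharing a 3-SNP, 68-bp cluster at an 8.75-fold activity ratio and 20,000
fragments per sample.  Matcher correctness is established by brute-force
substring scans on 10⁴-read libraries over the full 755-template panel.
These sizes were chosen to keep Monte-Carlo error a small fraction of the
effects under test while the full suite stays fast to run routinely.

## Known limitations

* The thermodynamic annotations use one fixed parameter set; published R²
  values between composition and read counts obtained with other Tm/ΔG
  parameterizations will not be reproduced digit-for-digit.
* Exact matching discards reads with any error inside the template; at
  high error rates depth loss is substantial (by design, accuracy is
  unaffected).
* Haplotype counting assumes reads derive from the declared amplicons; it
  does not detect chimeric fragments or template switching.
* eQTL P values are consumed as annotations only; no association testing is
  performed.
* No mismatch-tolerant alignment, UMI handling, PCR-duplicate removal or
  genome-wide peak calling — the scope is targeted panels with exact
  template structure.
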