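# Methods

This note records the models, parameter choices and numerical conventions
behind `heatmir`, and what the synthetic-data results do and do not say
about real libraries.

## Study design and units

The analysis is organised around a 16-library small-RNA design: two flower
organs (stamen, pistil) × two temperature regimes (CK = control, HS = heat
stress) × two sampling timepoints (2 d, 12 d) × two biological replicates.
Expression is counted per distinct tag (a trimmed insert sequence) and
normalised to TPM = count / clean-library-total × 10⁶, where the clean
total is the per-library read count after adapter/length/N/poly(A)
filtering and contaminant removal. All internal coordinates are 0-based
half-open; GFF3 output is 1-based inclusive.

## Preprocessing

Adapter trimming is deterministic by construction: the insert is the read
prefix before the leftmost exact occurrence of the adapter's first k = 8
bases; if no such occurrence exists, a terminal adapter prefix of ≥5 nt
flush with the 3′ end also counts. Reads whose insert is <15 nt or >40 nt,
contains N, or is ≥80% adenine (poly(A)-like; optional, on by default) are
discarded, each with an explicit reason so that raw = kept + Σ discarded
exactly. Contaminant matching is exact substring against the supplied
rRNA/tRNA/snoRNA/snRNA set and its reverse complement — no mismatches, so
a naive scan can serve as oracle; it is implemented by hashing every
contaminant window of the observed tag lengths.

## Folding

The built-in engine maximises, over all nested structures with a minimum
hairpin loop of 3 nt, the score

  score = Σ pairs s(i,j) + 1 per stacked pair,  s ∈ {GC: 3, AU: 2, GU: 1},

by an interval dynamic programme with an explicit "closed" table so the
stacking bonus is exact, and reports mfe = −0.5 × score as a
pseudo-energy. The DP optimum is provably identical to exhaustive
enumeration on short sequences (tested to length 18), and the traceback
structure always achieves the optimum. The tie-break (3′ base unpaired
first, then smallest bifurcation) makes the reported structure
deterministic.

Two caveats are deliberate. First, pseudo-energies are not thermodynamic
kcal/mol: on a 421-nt excision window the maximising engine pairs far more
than a thermodynamic model would, so window-level mfe values are large and
the −16 kcal/mol novel-miRNA threshold only becomes a sharp filter with
the ViennaRNA engine (`engine: vienna`), which is the pluggable
publication-grade alternative. Structure topology, which is what the
hairpin criteria consume, is much less sensitive to this choice than the
energies are. Second, only nested structures are considered — no
pseudoknots, no multi-strand folding.

## Hairpin criteria and star placement

A candidate passes when, in the folded window: the mature has partners on
exactly one side and overlaps no terminal loop; ≤4 mature bases are
unpaired; consecutive paired mature bases never flank an asymmetric bulge
of >2 nt; and the stem arm holding the mature is at least mature-length.
These thresholds follow common plant miRNA annotation practice and are
configurable (`HairpinCriteria`).

The star is inferred from the duplex geometry: starting from the paired
mature base nearest the mature 3′ end, the star start is extrapolated
along the duplex antidiagonal and shifted +2 nt, which yields 2-nt 3′
overhangs on both strands of a clean duplex; the placement is accepted
when at least half of the star positions pair back into the mature. A
novel call requires precursor mfe ≤ −16 and such a star placement;
`star_supported` additionally records whether the star was itself
sequenced. Whether unsequenced-star candidates should be rejected outright
is genuinely open in the field; the default here accepts structural stars
and exposes the flag.

## Dominant-read rule

Candidates are processed in descending peak-TPM order, and any candidate
whose hits all fall within an accepted record's locus (mature position
±220 nt, bounding the maximal stem extent for precursors ≤218 nt) is
absorbed as a fragment of that locus. This is what keeps star-arm, loop
and offset (isomiR-like) degradation reads from being annotated as
separate miRNAs. The cost is that genuinely distinct loci closer than
~220 nt would be merged; tandem clusters that tight are rare and the
margin is a parameter.

## Differential expression

The test is a Pearson chi-square (df = 1, no continuity correction) on
[[a, N_a−a], [b, N_b−b]] with replicate counts pooled per condition —
appropriate for count data at these depths, and equal to the textbook
N(ad−bc)²/(row × column margins) closed form, which the suite checks to
1e-9. Fold change is log₂((TPM_HS+ε)/(TPM_CK+ε)) with ε the TPM of one
pooled read, so zero counts stay finite; calls require |log₂FC| ≥ 1 and
raw p ≤ 0.05. Benjamini–Hochberg q-values are reported but do not gate
calls, matching the count-based sRNA-DE convention this reimplements; a
per-replicate mode (Fisher-combined) is available. Null simulation
(Poisson counts, equal expectation, 2000 replicates) puts the empirical
type-I rate at ~0.045–0.055, slightly conservative of nominal 0.05 because
of count discreteness.

The pooled chi-square treats biological replicates as technical — it
ignores overdispersion between plants. That is a faithful reimplementation
choice, not a statistical recommendation; with real replicate structure a
negative-binomial GLM would be the modern tool (out of scope here).

## Target scoring

Allen-style expectation: per miRNA position (1-based from the 5′ end)
mismatch 1.0, G:U wobble 0.5, gap 2.0, doubled at positions 2–13; a single
1-nt bulge on either strand is allowed; sites report at expectation ≤3.0.
A site is cleavage-competent when positions 9–11 all pair (wobble counts
as paired), and the cut coordinate convention is fixed as: the 0-based
transcript index of the base opposite miRNA position 10 (the base 3′ of
the cleaved bond). Worked duplex: a perfect 21-nt site occupying
transcript span [s, s+21) pairs miRNA position 1 at s+20 and position 10
at s+11, so the reported cleavage position is s+11; RACE clone 5′-end
positions must use the same convention.

## Synthetic data: what it emulates and what it does not

Planted precursors are perfect stem-loops (lower stem + mature arm + loop
+ reverse-complement arm, total 61–218 nt) with the star annotated at the
canonical 2-nt offset; mature sequences are mutually ≥4 mismatches apart,
three "known" loci carry 1–2 substitutions against their reference entry,
novel loci are ≥3 mismatches from every reference entry, and one novel
pair differs by 2 (a plantable family). Counts are Poisson with mean
TPM × depth/10⁶ (negative-binomial option off by default); star reads are
5% of mature abundance; contaminants are random windows of a synthetic
Rfam-like set (5% of depth); degradation background fills the remaining
depth with 15–40-nt genomic fragments. Baseline TPMs are log-uniform on
[50, 2000]; ten loci are down-regulated 4× (fold change 0.25) in every HS
library, emulating the uniformly-down heat response; two loci are
stamen-specific. The 3′ adapter defaults to a common kit sequence
(TGGAATTCTCGGGTGCCAAGG) since no adapter is prescribed by the design being
emulated; reads are insert + adapter truncated to 51 nt at fixed quality
'I'.

Degradation fragments are drawn without replacement over (start, length,
strand). With replacement, a 100-kb toy genome yields thousands of
coincidental duplicate fragments that clear the ≥10 TPM filter — an
artifact of the genome being ~4 orders of magnitude smaller than a real
one, where individual degradation products stay below any abundance
filter. Two realistic artifacts survive by design and are handled by the
pipeline rather than the generator: fragments of the two arms of a planted
hairpin collapse to identical tags (an inverted repeat reads the same from
both strands), and pseudo-adapter coincidences truncate distinct fragments
to one tag; both are absorbed by the dominant-read rule. A handful of
chance hairpins in random sequence can still be annotated as novel miRNAs
(~2 per 100 kb at these settings) — exactly the false-positive mode real
discovery pipelines have.

Passing on this generator therefore demonstrates correct bookkeeping,
classification logic and statistical calibration under the stated count
model; it does not demonstrate robustness to sequencing error, quality
artifacts, isomiR spectra of biological origin, RNA editing or repeat-rich
genomes, none of which are simulated.

## Problem sizes

The bundled study is a 100-kb genome, 30 loci, 16 × 200k reads; the full
pipeline runs in ~1–2 minutes and the complete test suite in ~2 minutes on
one CPU. Oracle cross-checks run at the scales where the oracles are
exact: folding enumeration to length 18, naive mapping on 50-kb genomes,
1000 random chi-square tables.

## Known limitations

- The exact mapper is memory-naive (full k-mer dictionary); fine to tens
  of megabases, not for a full plant genome in one dict.
- Known-miRNA matching is ungapped with ±2-nt slide; indel isoforms of
  reference matures are not matched.
- GO/KEGG annotation, degradome (PARE) analysis and phased-siRNA detection
  are out of scope.
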