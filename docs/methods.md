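# Methods

## Event model

Events are enumerated purely from annotation, by pairwise comparison of the
transcript isoforms of one gene. All coordinates are 0-based half-open
internally; GTF I/O converts at the boundary. Flank matching uses exact
splice-junction coordinates (upstream flank end, downstream flank start),
not full exon identity, because flank far boundaries routinely differ
between isoforms without changing the event. The four definitions:

- **SE** — an internal exon of the inclusion isoform, absent (as an exact
  interval) from the exclusion isoform, whose neighbouring junctions match
  a consecutive exon pair of the exclusion isoform.
- **MXE** — consecutive triples (u, a, d) and (u′, b, d′) with matching
  flank junctions, a absent from the second isoform, b absent from the
  first, and a, b non-overlapping. Both flank junctions must match; pairs
  with a single matching flank are not MXE (conservative: avoids
  double-counting near-SE configurations). The isoform carrying the
  genomically first exon is recorded as the inclusion form.
- **A5SS / A3SS** — two exons sharing one boundary and differing at the
  donor (5′) or acceptor (3′) boundary, adjacent to a shared junction. The
  `affected` interval is the differential *extension* only, with the
  short-form exon as the adjacent flank. This keeps a single invariant for
  all four types (affected strictly between the flanks) and makes n/N
  disjoint: the shared exon body counts toward N, the extension toward n.

Duplicate events across transcript pairs are collapsed on (type, affected
coordinates, flank junctions, strand), keeping the lexicographically
smallest (inclusion, exclusion) transcript pair — a pure determinism
tie-break. Enumeration is symmetric in transcript order and is checked
exactly against an exhaustive brute-force enumerator on random toy genes.

`acceptor_pos` is the strand-aware 5′ boundary of the (genomically first)
affected interval. For SE, MXE and A3SS this is the 3′-splice-site
position; for A5SS it is the donor-side extension boundary and is labelled
as such — acceptor-context analyses are intended for SE/A3SS/MXE sets.

Region classification (5UTR/CDS/3UTR/noncoding) uses the inclusion
transcript's genomic CDS bounds, strand-aware; any overlap with the CDS —
including boundary overlaps — classifies the event as CDS.

## Quantification and the 2×2 test

For one event and one condition, n is the mean per-base depth of the
affected exon (the genomically first exon for MXE) and N the mean depth of
the host transcript's exon union minus *all* affected intervals (for MXE
both exclusive exons are removed, keeping n and N disjoint). The inclusion
ratio is n/(n+N), bounded in [0, 1], so the 0.1 ratio-difference filter is
well-posed; the unbounded alternative n/N is available behind
`ratio_def="raw"` for users who prefer it. Events with an empty rest-exon
set (single-exon hosts) are skipped with a warning; events with n + N = 0
carry an undefined ratio, are flagged `low_coverage`, and are never
significant.

Two conditions are compared with a Pearson chi-squared test (1 df, no
Yates correction) on the table of mean coverages rounded half-up to
integers — the test expects counts and the statistic is tabulated directly
from coverages without length normalisation. Tables with a zero row or
column margin carry no evidence and return (χ² = 0, P = 1). Significance
requires both P ≤ `p_max` (default 0.1) and |Δratio| > `dratio_min`
(default 0.1); no multiple-testing correction is applied by default, with
Benjamini–Hochberg as an opt-in flag (the raw-P rule is the primary
analysis mode; the correction is offered for users who want FDR control).

Coverage is counted per aligned base (CIGAR M/=/X) of primary, mapped,
non-duplicate reads; split-read N gaps contribute nothing. No fractional
read assignment to isoforms is attempted — the statistic is coverage-based,
not an isoform-abundance EM.

### A statistical property worth knowing

The chi-squared test treats the tabulated values as counts. When the mean
coverage is averaged over a long exon of independently-sampled per-base
depths, its variance is far below Poisson (≈ depth/length), and the test
becomes strongly conservative under the null — practically no false
positives, at some cost in power near the thresholds. When each region's
coverage instead reflects a single sampling event (transcript-level
abundance sampling), the tabulated values are genuine Poisson counts and
the test is calibrated: at depth 50 the null rejection rate at P ≤ 0.1 is
≈ 0.10. The simulator exposes both regimes (below), and the calibration
study is run under the second.

## 3′-splice-site context

Windows span positions −35…−1 (intronic, AG at −2/−1) and +1…+5 (exonic);
there is no position 0. Minus-strand windows are reverse-complemented into
transcript orientation. Windows running off the contig are skipped with a
warning; windows without the canonical AG are kept but counted, since
annotations contain non-canonical acceptors. Frequencies are column-wise
nucleotide fractions with ambiguous bases excluded from the denominator.

The certainty transform is

    certainty(f) = clamp(log10(100·f / 2.4), 0, 1.5)  [bits]

i.e. the base-10 log of the percent frequency over a 2.4% background
floor. This convention reproduces the intended behaviour at both ends —
zero at or below the 2.4% floor, and approximately attaining the stated
1.5 ceiling at full conservation (log₁₀(100/2.4) = 1.62, clamped). Among
the candidate readings (natural log, log₂, fraction-scale argument) it is
the only one that is 0 at f = 2.4% *and* ~1.5 at f = 1; the residual
ambiguity is resolved by the clamp. A conventional information content
(max(0, 2 + log₂ f), in bits) is emitted alongside for comparability with
standard sequence logos. The polypyrimidine-tract summary is the mean C+T
fraction over positions −20…−3.

## 5′-UTR variants and uORFs

The inclusion-form 5′-UTR is spliced from the host transcript's exonic
bases upstream (transcript sense) of the CDS start; the exclusion form is
obtained by *subtracting* the affected interval(s) from it, rather than
splicing the exclusion transcript's own UTR. This guarantees the length
identity len(included) = len(excluded) + alt_exon_len even when the two
isoforms differ elsewhere, at the cost of ignoring unrelated UTR
differences between isoforms (which are not part of the event). Events
whose affected exon overlaps the CDS are rejected as misrouted.

A uORF is an ATG wholly within the UTR followed by in-frame triplets up to
the first stop codon (TAA/TAG/TGA). A stop strictly before the CDS start
gives a *terminated* uORF, reported when ≥ 9 nt (start codon + ≥ 1 codon +
stop; configurable). ORFs that reach the CDS start without a stop are
tallied separately as N-terminal extensions rather than uORFs — the
standard operational definition, stated here because published motif
scanners rarely print theirs. Overlapping uORFs are each counted from
their own ATG. The scanner is verified exactly against a regex-based
brute-force oracle.

5′-TOP detection — a transcript starting with C followed by ≥ 4 consecutive
pyrimidines — is reported in summaries but is a descriptive annotation
only; the motif has no universally agreed formula.

UTR summaries report, over significant events: the 5UTR/CDS/3UTR percent
distribution (noncoding events excluded from the denominator), mean 5′-UTR
length of coding transcripts with versus without catalogued events, the
mean alternative-exon share of the included UTR, and per-event uORF
count/mean-length deltas between the two UTR forms.

## Simulator

The generator lays out one gene per event on a single toy chromosome:
inclusion transcript [E1, E2*, E3, E4] (E2* the cassette, one of the MXE
pair, or the boundary-extended exon), exclusion transcript per the event
definition. Defaults: exon lengths 150–250 bp, introns 80–150 bp (always
≥ 40 bp so acceptor windows stay intronic), depth 50, ψ_A = 0.5 versus
ψ_B = 0.2 — a ΔPSI = 0.3 mid-range inclusion shift whose inclusion ratios
(1/3 vs 1/5, Δ ≈ 0.133) clear the 0.1 effect filter; shifts placed near
ψ = 1 (e.g. 1.0 vs 0.7, Δratio 0.088) are undetectable under the ratio
filter by construction, which is itself a documented property of the
bounded ratio. Events are assigned to CDS/5′-UTR/3′-UTR with probabilities
0.70/0.24/0.06, matching the region distribution reported for
differential-splicing surveys; strands alternate per gene.

Coverage: constitutive exonic bases at rate `depth`, the affected region at
ψ·depth, the MXE partner at (1−ψ)·depth, introns at 0 (optionally a small
Poisson noise floor). Two sampling models:

- `per_base` (default): every base an independent Poisson draw — smooth
  tracks, near-noise-free mean coverages; used for power/recovery studies.
- `per_region`: one Poisson draw per region, constant across its bases —
  transcript-level sampling under which the tabulated mean coverages are
  genuine Poisson counts; used for the null-calibration study.

Each event's acceptor window is overwritten with draws from a planted
position-probability motif (default: invariant AG at −2/−1, C/T
probability 0.85 across −20…−3, G-biased +1…+5, uniform elsewhere).
5′-UTR cassette genes carry a planted 12-nt uORF (ATG GCC GCC TAA) at a
known offset inside the alternative exon, recorded in the truth table.
The truth TSV stores per event: type, region, ψ per condition, expected
n/N and ratios (ψ·d, d, ψ/(1+ψ)), and planted uORF coordinates.

BAM emission (optional) peels the integer coverage profile layer by layer
into fully-aligned reads, so BAM-derived depth equals the bedGraph exactly;
it is a coverage carrier with no fragment-length, GC or sequencing-error
model. Everything is deterministic under the seed — identical configs give
byte-identical files.

What the simulator does *not* emulate: junction reads, biological
replicates, overdispersion beyond Poisson, shared exons between genes,
positional coverage bias, and novel (unannotated) junctions. Passing tests
therefore demonstrate correctness of the event algebra, the estimators and
the test under the stated sampling models — not robustness to the full
noise structure of real RNA-seq.

## Problem sizes and numerical choices

Default verification runs use: 10,000 random tables for the chi-squared
closed-form check (agreement to 1e−9; p-values to 1e−8 against numeric
integration), 200 random toy genes for the enumeration oracle, 2,000
events for null calibration (99% binomial band around the 0.1 nominal
level), 500 events for power (≥ 90% flagged; mean ratio within 0.03 of
ψ/(1+ψ)) and for motif recovery (per-cell 99% binomial intervals, with the
count of out-of-interval cells bounded by the 99.9% Binomial(160, 0.01)
quantile — demanding every one of 160 cells inside a 99% interval would
fail most seeds by construction), and 1,000 random sequences for the uORF
oracle.

Rounding before tabulation is half-up (floor(x + 0.5)). Zero-margin
tables return P = 1. The certainty of f = 0 is 0 (the clamp handles the
log singularity). bedGraph reading rejects overlapping intervals, naming
the first offending line; BAM reading requires an index and says how to
build one. Empty annotations yield an empty catalogue with a warning, not
an error.

## Known limitations

- Coverage-ratio PSI is a proxy: it conflates inclusion level with any
  coverage non-uniformity across the transcript, and (unlike
  junction-read methods) cannot separate overlapping isoform structures
  beyond the catalogued pair.
- The chi-squared on mean coverages is conservative for long exons under
  per-base noise (see above); users wanting calibrated P-values on real
  data should treat P ≤ 0.1 as a ranking filter, as the joint
  effect-size + P rule intends.
- Retained introns and alternative first/last exons are outside the event
  catalogue; GFF3 input is not supported (GTF only).
- uORF scanning assumes the annotated CDS start; upstream translation from
  non-AUG starts is not modelled.
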