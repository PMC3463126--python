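# Methods

This note documents the models, conventions and numerical choices behind
genomekit, in the order data flow through the package.

## Coordinate and file conventions

All internal coordinates are **0-based half-open** `[start, end)`; format
readers convert at the boundary (BED and refGene txStart/txEnd are native;
GFF and Biomart are 1-based inclusive and shifted on read; SAM POS is
1-based and shifted on read). Strand is `'+'`, `'-'` or `'.'`; an
unstranded `'.'` interval matches either strand even when strand agreement
is requested, so unstranded annotations (e.g. CpG islands) still annotate
stranded queries. Abutting half-open intervals do not overlap.

Line handling everywhere: `'\n'` separates lines, one preceding `'\r'` is
stripped on return (CRLF tolerance), and a final line without a newline
still counts as a line.

## Indexed file access

The line index records the starting byte offset of every line, found in one
sequential pass. The sidecar (`<file>.idx`) has a header line (source size,
mtime in ns, offset width) followed by one zero-padded 19-digit offset per
line, so entry *k* sits at a fixed byte position — entry lookup needs no
scan and almost no memory. Staleness is decided by comparing recorded size
and mtime against the source; either mismatch triggers a rebuild. This
header content and staleness rule are this package's convention. If the
sidecar cannot be written the index is kept in memory and a warning logged.
FASTA records may wrap; FASTQ is strictly 4 lines per record (wrapped FASTQ
is ambiguous and not supported).

## Table semantics

`Table` is a schema-typed columnar container restricted to four column
types (int, float, string, bool). Design points that were genuinely open:

* **Outer-join nulls.** There is no option type; missing sides are padded
  with per-type sentinels — `INT_MISSING = -2^63`, NaN, `""`, `False` —
  keeping the schema closed. Callers that need to distinguish a genuine
  `-2^63` from a null should not use int keys at that value.
* **Stable sort** is mandated (ties keep input order) so pipeline outputs
  are deterministic. Multi-key, mixed-direction sorts are realized by
  successive stable sorts from the least-significant key outward.
* **Joins** pair duplicate keys Cartesian-style (relational semantics) and
  build the key→rows map on the smaller operand; result rows are a-major.
* `smooth_column` (centered moving average, window shrinking at the edges)
  returns a float column even for int input, since means are not integers.
* `lower_bound`/`upper_bound` assume the column is sorted and do not check
  it (documented precondition, matching the usual binary-search contract).

## Coverage engine

Each mapped record passing the filters increments depth on every reference
base covered by its M/=/X CIGAR blocks; deletion (D) and skip (N) gaps are
not covered and cannot host mismatches (no read base exists there). Strand
comes from the reverse flag. Tracks are sparse maps per contig
(forward/reverse/total/mismatch), appropriate for mostly-empty genomes.

* **Uniquely aligning** means NH == 1 when the NH tag is present, else
  mapq > 0 — covering both aligner conventions for multi-mapper marking.
* **Midpoint mode** counts floor((start+end)/2) of the *outer* reference
  span (including D/N gaps), per read; its total mass therefore equals the
  number of counted reads.
* **Per-million normalization** multiplies depth (not mismatch counts —
  those are integer evidence tallies) by 1e6 / reads_counted, where
  reads_counted is the number of records passing the read-level filters,
  whether or not a region restriction later discards their bases.
* **Mismatches** come from MD tags walked jointly with the CIGAR: MD match
  and substitution tokens advance through the M/=/X reference positions (so
  insertions never shift the frame) and `^`-deletion runs are skipped.
  Records with absent or CIGAR-inconsistent MD are skipped and tallied.
* Duplicate-flagged (0x400) records are counted by default; a filter flag
  can exclude them.

## Annotation and counting

`annotate_tsv` never drops a row: in one-row mode matches are joined with
`';'` and rows without matches carry the explicit marker `'.'`; unknown
chromosomes annotate empty rather than erroring. Matched features appear in
deterministic (start, end, id) order.

Feature **shift** moves the window toward the feature's 5' end: positive
shift lowers coordinates on `'+'` (and unstranded) features and raises them
on `'-'` — the "probe the upstream promoter window" convention; coordinates
clamp at zero. A read overlapping N features increments all N (no
fractional assignment). RPKM follows the canonical definition
1e9·C/(N·L) with N the filtered read count and L the summed exon-block
length when sub-blocks exist, else the span length; zero-length features
get RPKM 0 with a warning tally. Whether overlapping features should share
a read is left to the caller's feature set; counting is per-feature.

## Wavelet ridge-line peak caller

**Signal preparation.** Coverage is summed into `bin_size`-base bins
(default 10), each track normalized to reads-per-million, the control (if
given) subtracted and negatives floored at zero — RPM-matched subtraction
is the simplest background combination that cancels identical tracks
exactly. An optional Gaussian or box pre-smoother is available but the
default is none: the wavelet transform itself does the smoothing, and an
unsmoothed signal lets the spike filter see single-bin artifacts at their
true width.

**Transform.** The wavelet is the Ricker (Mexican hat), the standard choice
for ridge-line peak detection. The scale parameter is calibrated in *bump
units*: scale s uses internal Ricker width b = √2·s and amplitude
normalization 1/b, which makes (a) the coefficient of a matched Gaussian
bump of sigma = s equal ≈ 0.965 × its amplitude at every scale, and (b) the
argmax over scales land at the bump's sigma (closed-form: the response at
width b to a sigma-σ bump is ∝ b²/(b²+σ²)^{3/2}, maximized at b = √2·σ).
The transform is dense (evaluated at every bin) — "translation-independent"
is interpreted as exact equivariance: shifting the input shifts every
coefficient array identically, up to boundary effects. Convolution uses
reflective padding to avoid spurious edge maxima; kernels are truncated at
±5b and re-centered to exact zero mean so constant signals give exactly
zero response. The default ladder is dyadic, 2–1024 bases; scales finer
than one bin or wider than the signal are skipped with a warning.

**Maxima and ridges.** At each scale, local maxima are positions strictly
dominating a centered window of width max(3, round(factor·scale_bins))
(default factor 1.0); plateaus resolve to their leftmost bin and positions
whose window is truncated by an array edge are excluded. Linking is greedy
from the largest scale down: each ridge extends to the nearest unclaimed
next-scale maximum within 0.5 × current-scale bins; competition is resolved
by larger current coefficient, then longer ridge, then smaller position;
equidistant candidates resolve to the smaller position. A miss increments a
consecutive-gap counter (reset on success); a ridge dies when the counter
exceeds the gap tolerance (default 2). Unclaimed maxima seed new ridges, so
every maximum belongs to exactly one ridge. The greedy step is provably
identical to exhaustively enumerating all feasible per-level matchings and
picking the one this preference order prescribes; the test suite checks
that equivalence on enumerable instances.

**Calling.** Ridges shorter than min_ridge_length (default 3) are dropped.
The summit is the ridge's smallest-scale position (best small-scale
localization); the score is the ridge length with the best coefficient as
tiebreak — the ranking rationale being that persistent-across-scales peaks
are isolated and well-formed. Peak boundaries walk outward from the summit
until the signal falls below half the summit height (or a local minimum
below the threshold), capped at ±2 × best scale; the boundary rule is this
package's convention. Two filters: *low-signal* drops summits below
min_signal — default `'auto'` = median + 5·1.4826·MAD of the signal, a
robust threshold that is positively homogeneous, so rescaling the signal
rescales the threshold and leaves the peak list invariant (amplitude
monotonicity) — and *spike* drops peaks whose full width at half maximum is
under 2 bins. Overlapping candidate calls are non-maximum suppressed (a
lower-ranked summit inside a kept peak's interval is dropped).

A single-scale Gaussian-smoothing caller (`gaussian_smooth_peaks`) is
provided for comparison under the same Peak contract.

## Synthetic data and what passing tests mean

The generators emulate idealized sequencing: uniform base composition,
uniformly placed reads, position-independent mismatch/indel rates with
consistent MD/NM tags, Poisson background coverage and Gaussian peak
profiles. Planted peak *width* is the full width at half maximum (the
convention peak widths are reported in); the Gaussian sigma is width/2.355.
The default planted-peak study — twenty 200-kb tracks, 20 peaks each,
widths 50–1000 bp, amplitudes 6–16 × the unit-Poisson noise SD — is sized
so each condition is unambiguous at desk scale while covering a 20-fold
width range; recovery requires the summit within half the planted width,
and a false positive is a call on true background (summit beyond one width
from every planted center).

These fixtures exercise the *accounting* of the methods (pileup arithmetic,
MD walking, interval algebra, ridge geometry), not the pathologies of real
libraries: GC bias, PCR duplicates, mappability holes, fragment-size
effects and correlated errors are absent, so passing tests bound algorithmic
correctness, not real-data performance.

## Known limitations

* On the flanks of very wide peaks the elevated signal floor can let
  small-scale noise ripples through the low-signal filter, producing short
  extra calls *within* a true peak's footprint (they are not background
  false positives and rank below the main call). A per-scale
  coefficient-SNR filter would remove them; it is not currently
  implemented.
* The half-max boundary rule under-reports the width of peaks on sloping
  backgrounds.
* Midpoint mode is per read, not per properly-paired fragment; paired-end
  fragment coverage is out of scope.
* The auto threshold assumes most bins are background; on tracks where
  peaks cover a large fraction of the genome it will inflate.
* Binary BAM/CRAM, bgzip virtual offsets and quality-aware pileup are out
  of scope; SAM is consumed as text.
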