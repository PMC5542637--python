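# Methods

## The amplicon model

LAM-PCR reads are modeled as single-direction amplicons anchored at a
vector-specific primer near the sequenced vector terminus (ITR end).
For an integration event at genomic position *p* with orientation *s*,
the amplicon is

    prefix + T(flank) + linker

where `prefix` is the vector sequence from the primer anchor through
the terminus, `flank` is the genomic sequence leaving the junction
(downstream on the plus strand for *s* = `+`, upstream
reverse-complemented for *s* = `-`), and `T` truncates at the cut
position of the nearest MseI (recognition `TTAA`, cut offset 1) or
MluCI (`AATT`, offset 0) site within `max_flank` bases. An event with
no site within `max_flank` yields no product: it is invisible to the
protocol, which is the dominant real-world recovery bias of
restriction-based LAM-PCR. Concatemer amplicons continue from the
terminus into the next vector copy — forward sequence for head-to-tail
junctions, reverse complement for the two inverted kinds (from the
anchored end head-to-head and tail-to-tail products are
indistinguishable, and the classifier only needs the binary call).

Reads are the first `read_length` bases of the amplicon, allocated to
amplicons by a single multinomial draw over clone abundances at total
`depth`, with i.i.d. substitution errors at `error_rate`. Paired ends,
indels, PCR bias, chimeras and quality degradation are not modeled:
the junction information in this assay is carried entirely by the
anchored single read, and substitution-only noise is what the
downstream Hamming-based matching has to absorb.

Clone abundances default to a Fisher log-series with θ = 0.95, giving
the heavy-tailed clonality in which a handful of clones carry a large
share of reads; `uniform` is available where tests need exact
expectations.

## Junction classification

A read is anchored by Hamming-matching the vector prefix at its 5' end
(≤ 2 substitutions). Past the anchor:

* if the next 12 nt exactly match any vector 12-mer (either strand),
  the read is a **concatemer**;
* otherwise the linker is located by a 10-nt prefix match (≤ 1
  mismatch) and trimmed; a remaining genomic fragment ≥ 20 nt makes an
  **IS** call (a missing linker is allowed — the read may end inside
  the flank before the cut site); shorter remainders are **internal**;
* reads without an anchor are **unclassified**.

The concatemer probe is exact by design. With a 1-mismatch budget the
vector's ~4,800 12-mers expand to a ~175,000-word neighbourhood, and
about 1% of random genomic flanks would collide with it and be thrown
away as concatemers — a direct loss of true sites. The asymmetric
failure mode of the exact probe is benign: a concatemer read with a
sequencing error inside the probe window falls through to the IS
branch, but its fragment is vector sequence and cannot reach the
mapping identity threshold on the genome, so it inflates no site.

`min_fragment` = 20 nt is the mappability floor (a 20-mer is
effectively unique in a multi-megabase random genome);
`max_flank` = 1000 nt bounds the restriction-site search.

## Mapping

Fragments are placed by exact 16-mer seeding against a 2-bit-packed
sorted k-mer array over both genome strands, followed by ungapped
full-length extension. Hits need ≥ 95% identity over ≥ 20 aligned
bases and are scored identity × aligned-length. A fragment is
**unique** when its best hit beats the runner-up by ≥ 5 score points;
otherwise every hit within the margin is a co-optimal locus and the
fragment is **multi**; no qualifying hit means **unmapped** (ungapped
extension deliberately sacrifices indel-bearing reads rather than
mis-placing them). The junction coordinate is the reference position
of the fragment base adjacent to the vector terminus — the aligned
span's start for plus-strand placements and its last base for
minus-strand placements — so the two orientations of one event
collapse to the same site.

## Sites, clonality and composition

Uniquely mapped junctions on the same chromosome and strand chain-merge
within a 3 bp window (alignment jitter tolerance; positions are exact
in this pipeline, so the window only has to absorb end-clipping).
Site position is the mode of member positions, ties to the smallest.
Clone size is the site's read count relative to all uniquely mapped IS
reads; multi-mapped fragments are excluded from quantification but are
counted — collapsed at their best placement — in the total/unique/multi
site accounting. Sample composition reports %IS and %concatemer of
vector-positive reads (IS + concatemer calls); with no vector-positive
reads the percentages are undefined (None), never zero. Site
persistence across serial samples matches sites between time points
with the same 3 bp window.

## Null models and statistics

The comparison distribution is a seeded synthetic random dataset
(default 8,628 positions). `uniform` samples positions uniformly over
the concatenated genome; `site_matched` samples uniformly among all
MseI/MluCI cut positions, reproducing the protocol's recovery bias in
the null (both recognition words are palindromic, so a plus-strand
scan suffices). Strand is a fair coin and is ignored by every test.

Fisher's exact test (two-sided, conditional on both margins) sums the
probabilities of all tables no more probable than the observed one.
For table totals ≤ 2000 the summation runs in exact integer/rational
arithmetic — table probabilities share the denominator C(n, c1), so
the "no more probable" comparison is an exact integer comparison and
tie handling is unambiguous. Larger tables use vectorized
hypergeometric pmf summation with a 1 + 1e-7 relative tie tolerance
(the scipy/R convention). The odds ratio is the sample cross-product
ratio, with 0/0 reported as NaN.

The hotspot scan builds one on/off-chromosome table per chromosome
against the null and controls the FDR across chromosomes by
Benjamini–Hochberg (configurable: none / Bonferroni / BH; BH is the
default as the field standard — no correction method is prescribed by
the protocol itself). Gene context assigns each position to distance
bins {in gene, ≤ 10 kb, 10–100 kb, > 100 kb} from the nearest gene
span; distributions are compared per bin by Fisher with BH. Cancer-gene
enrichment counts positions strictly inside cancer-flagged gene spans
(no promoter extension by default; the flag generalises curated
cancer-gene lists to a user-supplied name list).

## Default study conditions

The shipped defaults define the simulated study: a 2 Mb toy genome
(chromosomes of 1.5 Mb and 0.5 Mb, GC 0.41), 120 non-overlapping 5 kb
genes (30% of the genome genic) of which 30% are cancer-flagged — so
~9% of the genome lies in cancer-flagged spans, putting the null
cancer-gene fraction near 9% — 200 planted events, 20,000 reads,
concatemer abundance at 10% of recoverable IS abundance (a realized
IS share of ~90% of vector-positive reads), and an 8,628-position
uniform null. The synthetic vector (seeded random 2.4 kb, 24-nt
terminal anchor) and linker (30 nt, free of TTAA/AATT so the adaptor
itself cannot be cut) are stand-ins: any real construct and adaptor
can be supplied, and the linker is validated at load to share no
≥ 10-nt substring with the anchor.

What the simulator does not emulate — PCR amplification bias,
chimeric reads, homology between vector and host genome, indel
errors — bounds what green tests mean: they demonstrate the
correctness of the junction logic, the mapping partition and the
statistics on data matching the stated error model, not robustness to
every artifact of real libraries.

## Numerical and degenerate-input choices

Sorting keys make every stage deterministic under a fixed seed: hits
by (−score, chrom, pos, strand), sites by (chrom, pos, strand),
top-N by (−read count, chrom, pos). Collapsing is idempotent.
Degenerate inputs fail loudly: empty FASTA, duplicate record names,
out-of-bounds features, all-zero Fisher tables, hotspot windows
outside the genome, and single-time-point persistence queries all
raise with the offending name in the message. Stage manifests record
the seed and a hash of all result-affecting parameters (the output
directory is excluded, so identical runs into different directories
are byte-identical).

## Problem sizes

Tests and the acceptance script run the full pipeline at the default
2 Mb / 20,000-read scale and the statistics at 200 replicate seeds per
error-rate check; these sizes give binomial/multinomial tolerances of
a few percent (4σ bands) while the whole suite stays interactive. The
brute-force mapping oracle is applied on ≤ 100 kb genomes where
exhaustive scanning is exact and cheap.
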