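# lamsite

Integration-site analysis for AAV gene-therapy vectors from LAM-PCR
(linear amplification-mediated PCR) sequencing reads — with a
ground-truthed read simulator, so every stage of the pipeline can be
verified without access to proprietary sequencing data.

## The problem

Recombinant AAV vectors persist mostly as episomes, but a fraction of
vector genomes integrates into host chromosomes. For long-term safety
surveillance (is expression driven by integrated provirus? are
integrations clustering near cancer genes?) the standard readout is
LAM-PCR: a vector-specific primer anchors linear amplification across
the vector–genome junction, amplicons are truncated at the first MseI
(T^TAA) or MluCI (^AATT) restriction site, a linker is ligated, and
nested PCR products are sequenced. Each read therefore looks like

```
[vector anchor ... ITR terminus][genomic flank up to the cut][linker]
```

for a true integration site (IS), or continues into more vector sequence
for a vector–vector (concatemer) junction from episomal multimers.
`lamsite` implements the complete downstream analysis:

1. **simulate** — a toy genome plus planted integration events with
   skewed (log-series) clonal abundances and concatemeric episomes,
   rendered into error-bearing FASTQ reads with a per-read truth table;
2. **call** — quality filtering, vector-anchor detection (Hamming
   matching), and per-read classification into
   IS / concatemer / internal / unclassified;
3. **map** — k-mer seed-and-extend placement of genomic fragments on
   the reference, resolving uniquely mappable junctions from
   multi-locus ones by a score margin;
4. **quantify** — collapsing junctions into integration sites, clone
   sizes as read counts relative to all uniquely mapped IS reads,
   per-sample composition (%IS vs %concatemer of vector-positive
   reads), and site persistence across serial samples;
5. **test** — comparison against a synthetic random null (uniform, or
   matched to restriction-site positions): per-chromosome hotspot scan,
   gene-distance context distribution, and cancer-gene enrichment, all
   by Fisher's exact test with Benjamini–Hochberg control.

The statistical core is the 2×2 Fisher comparison of observed sites
against *N* random null positions, e.g. for cancer-gene membership

```
            in cancer gene   outside
sample           a              b
null             c              d
```

with the two-sided p summing hypergeometric table probabilities no more
probable than the observed table (exact rational arithmetic for small
tables). Vector copy number follows the standard normalisation of qPCR
copies per 6.6 pg genomic DNA per diploid cell.

## Worked example

```python
from lamsite import simulate, junctions, mapping, clonality
from lamsite.model import SimulationConfig, DEFAULT_ENZYMES
from lamsite.pipeline import default_concatemers

genome, genes = simulate.make_toy_genome(2, [400_000, 200_000], n_genes=36, seed=7)
vector, linker = simulate.default_vector(), simulate.DEFAULT_LINKER
cfg = SimulationConfig(n_events=50, depth=5_000, error_rate=0.0, seed=7)
events = simulate.plant_integrations(genome, cfg)
rec = sum(e.abundance for e in events
          if (fl := simulate.event_amplicon(genome, e, vector, linker,
                                            DEFAULT_ENZYMES, cfg.max_flank)[1])
          and fl >= cfg.min_fragment)
reads, truth = simulate.lam_pcr_reads(events, default_concatemers(rec, 0.1),
                                      genome, vector, linker, DEFAULT_ENZYMES, cfg)
calls = junctions.classify_reads(reads, vector, linker)
mapped = mapping.map_junction_calls(calls, mapping.build_index(genome, 16))
sites = clonality.quantify(clonality.collapse_sites(mapped))
summary = clonality.summarize_sample(calls, mapped, sites, "demo", "t0")
```

This prints (via the obvious format calls):

```
reads: 5000   IS reads: 4221   concatemer reads: 452
sites: 43 (43 unique, 0 multi)
composition: 90.3% IS / 9.7% concatemer
  chr1:90119 (-)  reads=453  rel=0.109
  chr1:214797 (+)  reads=426  rel=0.102
  chr1:193821 (-)  reads=328  rel=0.079
```

43 of the 50 planted clones had a restriction site close enough to the
junction to be recoverable by the protocol, and all 43 come back as
uniquely mapped sites at their exact planted coordinates. The
composition (90.3% IS) recovers the configured 10% concatemer abundance
share, and the three most prominent clones carry ~29% of all uniquely
mapped IS reads — the read-count skew injected by the log-series clone
model.

The same run is available from the shell:

```sh
lamsite all --seed 7 --outdir out/
```

which chains `simulate → call → map → quantify → test → report` and
writes TSV/BED/FASTQ artifacts plus per-stage JSON manifests; `lamsite
report` renders the top-10 clonality table and the chromosome
distribution against the null.

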