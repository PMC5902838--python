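# Methods

## The detection model

GC-biased gene conversion (gBGC) is the hypothesis that the mismatch-repair
machinery resolving heteroduplex DNA during meiotic recombination favors
G/C ("strong", S) over A/T ("weak", W) alleles. In phased population data
its footprint is a **SNP flip-over**: a single allele replaced by its
counterpart inside an otherwise conserved haplotype.

`gcflip` detects candidate flip-overs as follows:

1. **Variant filtering** (`variant_io`). Only biallelic records with fully
   phased, non-missing diploid genotypes for every sample are used.
   Multi-allelic, unphased or partially missing records are skipped and
   tallied, never errored on — imperfect inputs should not corrupt the
   haplotype strings. Allele frequency comes from the `AF` INFO tag when
   present and is otherwise computed from genotypes. The frequency filter
   keeps variants with minor-allele frequency **strictly greater than
   0.25**; a site at exactly 0.25 is excluded. Both SNPs and indels pass
   this filter and enter haplotype construction; only the acceptor site
   itself must be a SNP. Autosomes only by default.

2. **Haplotype cataloging** (`haplotype_catalog`). Per chromosome, the
   frequent variants are cut into consecutive segments of exactly *k* = 50
   variants; a trailing remainder shorter than *k* is dropped and counted
   (the detector needs fixed-length strings). Segmentation is by variant
   count, not physical span — an optional maximum-span guard exists but is
   off by default. Each of the N individuals contributes two strings of
   0/1 allele codes per segment (one per parental chromosome); the catalog
   ranks distinct strings by occurrence (ties broken lexicographically for
   determinism) and labels them **common** (count ≥ 100), **rare**
   (count ≤ 5) or intermediate. The thresholds are absolute counts, sized
   for populations of roughly a thousand individuals, and are exposed in
   configuration; they do not rescale with N automatically.

3. **Flip-over detection** (`flipover_detector`). The Hamming-1 comparison
   is made **within an individual**, between their two parental
   haplotypes: one must be common, the other rare (the "acceptor"
   haplotype), they must differ at exactly one position, and the differing
   variant must be a SNP. Because the other *k* − 1 sites match, the
   carrier is homozygous everywhere except the acceptor site — a genotype
   configuration that statistical phasing cannot scramble, which is the
   point: it removes phasing error as a confounder. The base change is
   read common → rare (the rare haplotype is assumed derived) and
   classified by the W/S partition: W→S, S→W, or no-base-change (W→W,
   S→S). Events are counted per qualifying carrier; a per-distinct-
   acceptor count is available alongside (`distinct_acceptor_count`)
   since either convention is defensible. Occurrence categories "1", "2",
   "1-2", "1-5" restrict the acceptor count.

4. **Bias statistics** (`bgc_stats`). With a = W→S and b = S→W counts, the
   excess is `100·(a − b)/((a + b)/2)` — the difference relative to the
   *mean* of the two counts. This denominator is chosen because it is the
   unique convention consistent with the jointly reported count pair and
   headline percentage this pipeline is meant to reproduce (difference
   over the smaller count gives 12.5%, over the larger 11.1%, over the
   mean 11.7%); a test pins the convention. The standard error of
   p = a/(a+b) is the rule-of-sample-proportions `sqrt(p(1−p)/N)`; on the
   bias-percent scale (bias% = 200p − 100) the delta-method SE is
   `200·SE(p)`, and both are reported. Significance of the asymmetry is a
   1-df chi-square goodness-of-fit against a 50:50 split,
   `χ² = (a−b)²/(a+b)` — inherently two-sided in the deviation — with an
   exact binomial test available as a cross-check. Display of vanishing
   p-values is floored at `<1e-16`.

5. **Local GC context** (`local_gc`). Each event's context is the
   reference GC fraction of the 50 bases before and after the acceptor
   site (100 bases, focal base excluded; a 101-base mode including it is
   available since the convention is ambiguous). Windows crossing contig
   edges or with > 10% N are skipped, not imputed. Classes are
   downsampled (seeded) to equal n and compared against the same number
   of control sites drawn uniformly from the union of analyzed segment
   spans — controlling for the detector's genomic footprint; a
   whole-chromosome control mode can be had by passing different regions.
   Distributions use 2% GC bins by default. Goodness-of-fit is chi-square
   with the control as the expected distribution, pooling adjacent bins
   until every expected count is ≥ 5.

6. **Per-gamete expectation model** (`gamete_model`). A closed-form
   arithmetic chain: events/generation × mean tract length gives total
   heteroduplex DNA per gamete (NCO: 228 × 75 bp = 17.1 kb; CO: 30 ×
   600 bp = 18 kb); dividing by the mean heterozygous-site spacing
   (1.2 kb) gives expected mismatches (14.25 and 15); half of mismatches
   resolve to the partner allele (flip-overs: ≈7.1 from NCOs; total base
   changes from both pathways: ≈14.6); the observed outcome fractions
   (45.7% W→S, 38.9% S→W, 15.4% no change — injectable from a
   `BiasSummary`) split the total into ≈6.7 / 5.7 / 2.25 events, a net
   gain of ≈1 GC pair per gamete. Internally nothing is rounded;
   `printed_chain()` renders the chain at one decimal, recomputing the
   class split from the *rounded* total so the displayed figures multiply
   out consistently (14.6 × 0.154 → 2.2, where the unrounded
   14.625 × 0.154 = 2.252 would display as 2.3 beside a total shown as
   14.6).

## Synthetic data: what it emulates and what it does not

The generator (`synthetic_data`) reproduces exactly the structure the
detector's contract assumes: each segment's 2N haplotypes are drawn from a
few founder haplotypes (default 3, frequencies 0.4/0.3/0.3) assigned in
exact largest-remainder proportions and shuffled; planted events give each
chosen carrier the donor founder on one parental chromosome and a copy of
the donor mutated at the acceptor site on the other. Founders are kept
**≥ 3 mismatches apart**, so no founder pair and no (founder, acceptor)
pair can accidentally sit at Hamming distance 1 — planted-event recovery
is therefore exact by construction, and sensitivity = precision = 1.0 is
the pass criterion, not a target to approach. Site allele patterns are
restricted so every realized MAF stays above 0.25 even after planting
perturbs a few haplotypes; the generator verifies this when writing and
refuses configurations that break it. AF tags hold realized
genotype-computed frequencies. Optional "noise" haplotypes (a founder
mutated at two sites, kept ≥ 2 mismatches from every founder) exercise
specificity.

Defaults were chosen once as a realistic desk-scale population: 200
individuals, 10 segments of 50 variants, ~1 kb mean spacing (so a segment
spans ~50 kb, the scale at which common-haplotype blocks are observed in
human data), genome GC 0.45. A 200-individual population yields founder
occurrence counts of 160/120/120 haplotypes, all above the absolute
common threshold of 100.

What the generator does **not** model: coalescent genealogy,
recombination maps, LD decay within segments, mutation-rate or GC
heterogeneity beyond the piecewise GC profile, genotyping error, or
population structure. Passing tests therefore demonstrate the pipeline's
correctness on its own assumptions — that detected events are exactly the
individuals carrying a common/acceptor pair — not the biological error
rate of those assumptions on real cohorts, where recurrent mutation,
gene-conversion-free homoplasy and residual sequencing error all enter
the rare-haplotype tail.

## Numerical and design choices

- Coordinates: 1-based inclusive at every interface (VCF/FASTA
  convention); 0-based half-open only inside array arithmetic.
- Catalog ordering and event ordering are fully deterministic (count
  descending, then allele string; chrom, segment, sample order), so
  pipeline reruns are byte-identical.
- Chi-square on one degree of freedom is used even for very large counts;
  no continuity correction (the exact binomial cross-check is provided).
- The bias denominator convention (mean of the two counts) and the strict
  MAF inequality are fixed by tests, not configuration.
- Degenerate inputs: empty event lists summarize to zero counts with
  statistics `None`; windows at contig edges are skipped; an empty
  distribution cannot be tested and raises.
- Problem sizes in the test suite (200 individuals × 10 segments for
  recovery sweeps; k ≤ 8, N ≤ 16 for the exhaustive oracle; 50 random
  oracle instances; 20 recovery seeds) were sized to exercise every code
  path with exact, enumerable expectations.

## Known limitations

- Absolute common/rare thresholds assume a ~1000-genome cohort; smaller
  panels must rescale them explicitly (both are plain parameters).
- The detector cannot distinguish a true non-crossover conversion from a
  recurrent mutation on a common-haplotype background; the occurrence
  categories (1, 2, 1–2, 1–5) bound, but do not eliminate, sequencing
  error and recurrence.
- Events are attributed per carrier; a single ancestral conversion
  inherited by several carriers is counted several times under the
  default convention (the distinct-acceptor count is reported alongside).
- The per-gamete model is a point arithmetic chain; it propagates no
  uncertainty in its rate parameters.
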