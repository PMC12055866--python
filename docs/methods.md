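# Methods

`ampliphase` models and analyses single-amplicon long-read phasing of the
GSTA1 proximal promoter. This note records the models, their assumptions,
the default parameters and the numerical choices, so that every number a
run produces can be traced to a documented decision.

## The amplicon and its SNP catalog

The target is a 1336-bp PCR product mapped to GRCh38
chr6:52803791–52805125 containing six biallelic SNPs: rs3957356 (−52),
rs3957357 (−69), rs11964968 (−513), rs4715332 (−567), rs4715333 (−631)
and rs58912740 (−1142), where the numbers are promoter-relative
positions. The reference (first-listed) alleles G, C, A, T, T, C define
the *A1 haplotype; the alternates A, T, G, G, G, G define *B1b; *A2
differs from *A1 only at −631 and *B1a from *B1b only at −513.

Two coordinate quirks are carried as-is rather than resolved:

- the stated genomic span covers 1335 bases (1-based inclusive) while the
  product is described as 1336 bp; the product length is authoritative
  for all simulation and alignment, and both values are recorded on the
  reference object;
- the promoter labels give a maximum inter-SNP distance of
  |−52 − (−1142)| = 1090 bp, whereas the distance is sometimes quoted as
  1089 bp; distances here are always computed from the labels, and the
  1-bp discrepancy is simply noted.

The primer/TSS coordinates needed to place the promoter scale onto the
amplicon exactly are not published, so the default offset map is the
rigid translation `offset = promoter_pos + 1142 + 120`, which keeps every
SNP ≥ 120 bp from either end. It is configurable through the SNP-catalog
TSV. Because the map is rigid, label distances and offset distances are
identical. The reference background sequence is a seeded random sequence
with the catalogued alleles planted (synthetic); no pipeline statistic
depends on the non-SNP bases.

## PCR amplification with template switching

The pool starts from `n0_per_haplotype` molecules per haplotype. Each
cycle, a molecule duplicates with probability

    e_c = efficiency0 · max(0, 1 − pool/K)

(logistic plateau with capacity `K`), and each new strand is the product
of a template switch with probability

    chi_c = chimera_rate0 · min(1, pool/K).

A switch picks a breakpoint uniformly on [1, L−1] and copies the suffix
from a uniformly drawn other pool molecule; mosaics compose, so
late-cycle molecules can carry several breakpoints. A molecule is
*chimeric* when its merged mosaic contains both haplotypes; a switch
between content-identical molecules yields a non-chimeric product.

The mechanism encodes two qualitative observations about hybrid
haplotypes in amplicon PCR: the number of cycles past the plateau drives
hybrid formation, while extension/annealing time and input DNA amount
have little effect. Extension and annealing time are therefore
deliberately *not* parameters of the model. Whether real switch
breakpoints are uniform is unknown; uniformity is a declared model
assumption, not a claim about the chemistry.

Defaults (chosen once, at desk scale):

| parameter | default | rationale |
|---|---|---|
| `n0_per_haplotype` | 75 per 20 ng (linear in ng) | ~3.75 molecules/ng; only relative input matters for the sweeps |
| `efficiency0` | 0.30 | places the yield plateau near cycle 25, where low-cycle PCRs were observed to stop producing sequencable DNA |
| `capacity K` | 1e5 molecules | small enough to simulate molecule-by-molecule, large enough for <1% Monte-Carlo noise |
| `chimera_rate0` | 0.5 per new strand at full plateau | produces hybrid loads (~20% of molecules after 40 cycles) of the magnitude implied by the long-distance phase degradation seen in real amplicon data |
| `cycles` | 40 | the standard protocol length |

The pool is a scaled-down surrogate: real reactions traverse ~1e10
molecules. Pure molecules of a haplotype are exchangeable, so the pool
is stored as two counts plus an explicit list of chimeric mosaics; this
compact form is distribution-identical to a molecule-by-molecule
simulation (verified against a naive oracle in the tests). The yield
threshold for "enough DNA to sequence" is 35,000 molecules (~K/3, the
geometric midpoint between the expected 20- and 25-cycle yields), on
which 15- and 20-cycle reactions at the 20-ng default input are flagged
insufficient. At 120 ng the model lets a 20-cycle reaction clear the
threshold; the published observation does not separate the two input
arms, and the insufficiency checks here are made at 20 ng.

## Read model

Each read samples a pool molecule uniformly (plus strand); each end is
truncated independently with probability `trunc_prob` by an amount
uniform on {0..trunc_max} bp; reads whose truncated template is shorter
than `min_len` = 50 bp are rejected and redrawn. Errors are uniform:
substitutions (5%) over the three alternative bases, insertions (1%) and
deletions (1%) — roughly nanopore-like magnitudes with no positional or
homopolymer structure. FASTQ qualities are a constant Phred score
implied by the total error rate. A truth sidecar records molecule of
origin, mosaic, truncations and error counts per read.

`trunc_prob = 0.654` and `trunc_max = 897` were solved by exact
enumeration of the truncation distribution (including the min-length
rejection) so that default reads of the 1336-bp amplicon have a mean
length of ~813 bp and relative depth ~0.50 at both amplicon ends — the
read-length and coverage profile this pipeline is meant to emulate.
A naive two-parameter choice cannot hit both observables
simultaneously because maximum depth sits mid-amplicon at only ~2/3 of
the read count; the enumeration solves the exact system, and the test
suite re-checks both observables by simulation. What the generator does *not* emulate: reads longer
than the amplicon (real data contain rare multi-kb outliers, presumably
concatemers), strand mixtures, quality-score profiles, barcode
artefacts, or polymerase point errors arising before sequencing.

## Alignment

A banded semiglobal affine-gap aligner replaces a general-purpose mapper:
end gaps on the reference are free, the entire read must align. Scoring
is match +2, mismatch −4, and a gap of length g costs −4 − 2g. The band
is centred on the best diagonal voted by exact 15-mer seeds; alignment
first runs with half-width 16 and widens to the configured band (default
64) if the aligned identity falls below 0.75 — at ≤7% error the net
diagonal drift over 1336 bp has a standard deviation of ~5 bp, so the
narrow band almost always suffices. Reads without seed support fall back
to an unbanded alignment on both strands. A read is unmapped below 0.6
aligned identity (permissive for 5–7% error reads, strict enough to
reject unrelated sequence). Terminal ties prefer the smaller reference
end position; the forward strand wins strand ties. The banded kernel is
checked against an exhaustive oracle that globally aligns the read to
every reference substring. SAM import/export (pysam) allows substituting
any external aligner.

## Genotyping and the 1/3 filter

Per-read alleles are read off the CIGAR at the six catalogued offsets;
a deletion over a site gives a missing call, insertions never shift the
assignment. At each site, a base is retained iff its count is ≥ 1/3 of
the reads covering the site ("below 1/3" discards, implemented in exact
integer arithmetic: retain iff 3·count ≥ coverage); reads carrying
non-retained bases are excluded from that site. The filter is applied
once per site, before all pair analyses. At most two alleles can exceed
a strict third, so calls are het (2 retained) or hom (1 retained); the
exact three-way-thirds tie retains all three and is flagged
`ambiguous_thirds`; a call that discards ≥ 1/3 of its reads is flagged
`low_confidence`. Sites need ≥ 20 covering reads (far below the ~800×
depth of a typical run, configurable) or they no-call. There is no
likelihood model and no indel calling — counts and the threshold are the
entire caller, by design.

Read statistics follow the conventional precision: mean length to one
decimal, percent-of-amplicon to one decimal computed from the unrounded
mean, percent mapped to two decimals. Published per-sample rows do not
all recompute exactly from their printed rounded means, so aggregation
recomputes from counts and unrounded means.

## Pairwise concordance and its decay

For a pair of heterozygous sites with retained alleles (a1,a2) and
(b1,b2), informative reads (retained allele at both sites) fill a 2×2
table. The two perfect matchings {(a1,b1),(a2,b2)} and
{(a1,b2),(a2,b1)} are scored by their read counts; `prop_correct` is the
larger count divided by informative reads. The statistic is therefore
≥ 0.5 by construction, symmetric in the two sites and invariant under
allele relabelling. "Correct" is defined as the majority matching: with
known truth these coincide in all studied samples, and without truth
the majority matching is the only available definition. An exact tie is
flagged ambiguous and reported with the lexicographically smallest
matching.

True molecules always support one matching, so clean data give 1.0 at
every distance; chimeric molecules whose breakpoint falls between the
two sites support either matching at random, pulling the proportion
toward 0.5 in proportion to hybrid load times breakpoint probability —
hence the monotone decay with inter-SNP distance. Sequencing errors add
a distance-independent floor.

The hybrid-rate estimator makes the decay quantitative: the error floor
is the informative-read-weighted mean discordance of pairs closer than
200 bp, the per-pair excess is max(0, discordance − floor), and the
per-bp rate is the least-squares through-origin slope of excess against
distance. It is a summary statistic, not a mechanistic inverse; tests
require only that it ranks hybrid loads correctly.

## Exhaustive diplotype phasing

With k heterozygous sites (k ≤ 12 enforced), all 2^(k−1) phase
configurations are enumerated; a configuration scores the sum over reads
of the better of the agreements with its two haplotypes, counted over
each read's covered het sites with retained alleles. The argmax is the
called diplotype; homozygous sites are filled directly, no-call sites
yield N with a flag. Score ties are flagged and broken
lexicographically on haplotype 1 (whose first het-site allele is fixed
to the alphabetically smaller one to factor out the H1/H2 symmetry).
The enumeration is exact and is verified against an independent
re-scanning scorer in the tests.

Star naming is exact-match lookup into the four-haplotype table, with
"unassigned" for anything else; the A-family name is written before the
B-family name and identical haplotypes are joined with a slash
("*A1/*A1"). Haplotypes such as *A3/*B2 that the six-SNP catalog cannot
distinguish from data are excluded from the default table (extensible
via TSV). Which side of an unphased genotype pair belongs to the
A-family is derived from cross-sample consistency (the reference-like
side), a derivation, not a published statement.

## Problem sizes and reproducibility

Simulated studies in the test-suite and acceptance script use: 100 seeds
× 5000 reads for the decay-direction property; 40 paired replicates ×
5000 error-free reads per switch-probability level for estimator
ranking (error-free so the chimera signal at χ0 ≤ 0.01 is not swamped by
the error floor); 100 seeds per condition for the cycle/input sweep; and
10,000 reads for read-model calibration checks. These sizes were chosen
for comfortable statistical margins at desk scale.

One integer seed governs any run; stage seeds derive from CRC32 of
`(seed, stage)`, so a stage can be rerun in isolation and full runs are
byte-reproducible (the report embeds the config hash).

## Known limitations

- The chimera mechanism is a one-parameter phenomenological model; it
  reproduces directions and relative magnitudes, not chemistry. Real
  per-bp hybrid rates cannot be read off `chimera_rate0`.
- The error model has no sequence context; identity thresholds tuned
  here may need revisiting for data with strong homopolymer errors.
- Genotyping is count-threshold only and biallelic-SNP only; it is not
  a general variant caller.
- The star table covers only the four haplotypes the six SNPs can
  distinguish from read data.
- Phasing is per-amplicon; there is no multi-amplicon or population-LD
  phasing.
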