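# Methods

## The mapping design

A haploid strain evolved under selection carries a set of evolved-specific
point mutations. Crossing it to its unevolved parent and sporulating the
transient diploid yields tetrads in which every heterozygous site segregates
2:2. Repeated backcrossing with phenotype-based selection of one segregant
per round keeps the causal alleles while each neutral evolved-specific
mutation survives round *k* with probability 0.5^k — after three rounds
87.5 % are expected to be gone. Sequencing the trio (parent, evolved,
final segregant) and classifying each reliable evolved-specific variant as
*lost in backcross* versus *segregating* therefore concentrates causal
candidates in the small segregating set. All package components exist to
simulate, execute, or quantify parts of this design.

## Meiosis model

Meiosis is simulated at the four-chromatid level. Each parent contributes
two sister chromatids (four physical lines); the number of crossovers per
chromosome is Poisson with mean `recombination_rate`, positions are uniform,
and each crossover joins one uniformly chosen line of each parent — no
crossover or chromatid interference. The four meiotic products are read off
by walking each centromere rightward and switching lines at every crossover
involving the line currently followed; the product↔line mapping is a
permutation at every coordinate, so 2:2 segregation is exact at every site,
sister products are complementary, and the classical two-locus consequences
hold: for unlinked loci E[PD] = E[NPD] and P(TT) = 2/3 in the
far-from-centromere limit (products are assigned to spores by a uniform
permutation per chromosome, so centromere linkage is not modelled); for an
interval with expected crossover count *m*, P(TT) = ⅔(1 − e^(−3m/2)) and the
Perkins estimate 100·(TT/2 + 3·NPD)/total recovers the map distance 50·m cM
at moderate distances. An earlier draft exchanged material between
centromere-attached molecules instead of physical lines; that model
deflates TT when crossovers flank the marker interval and was rejected
against the closed-form expectation above.

No recombination map is imposed: crossover count per chromosome is a single
rate (default 6, the magnitude typical of a yeast chromosome), which is all
the design's statistics require.

## Default genome and mutation process

The default genome has 16 chromosomes with S288C-like relative lengths
scaled to 12 Mbp. The neutral mutation process is
Poisson(total_bp × rate × generations) with defaults rate = 10⁻⁹ per bp per
generation (the upper end of the natural yeast range) and 50 generations.
Because the observed evolved strain carried ten evolved-specific variants —
more than the natural-rate expectation of ~0.6 — cohort-level simulations
(`simulate_mapping_cohort`) accept an explicit `n_neutral` and use 8
neutral mutations plus the two causal loci when emulating the mapping
experiment; the rate stays a free parameter rather than being tuned to
match that count.

## Phenotype model

Growth on glycerol is a two-locus epistatic lookup with defaults taken from
the allele-replacement measurements: µ_max = 0 (neither causal allele),
0.060 h⁻¹ (GUT1-only), 0.033 h⁻¹ (UBR2-only), 0.130 h⁻¹ (both — more than
the sum of the single effects). The double-mutant lag defaults to 15 h (the
measured value for the backcrossed segregant); single-mutant lags (30/40 h)
and the no-growth lag (0, meaningless at µ = 0) are package choices — the
source measurements report lags only graphically. Any non-reference allele
at a causal locus counts as the causal allele (each causal locus carries a
single mutation).

Backcross selection screens 28 segregants per round by default (the
experiment's screening size) and picks the highest µ, ties broken by lowest
segregant index. With 28 screened, the probability that all three rounds
retain both causal alleles is (1 − (3/4)²⁸)³ ≈ 0.999; at the 20-segregant
lower bound sometimes quoted for such screens it is ≈ 0.99, too marginal to
assert over finite replicates, so reliability tests run at 28.

## Genotype-call noise

Per-sample read depth is negative-binomial around `mean_depth` (default
100×, matching the trio's 85–157× sequencing) with variance
mean + dispersion·mean² (dispersion 0.1 ≈ 33 % coefficient of variation;
0 makes depth deterministic). A call is a majority vote of `depth` reads
each wrong with probability `base_error_rate` (default 10⁻³), ties broken
by a fair coin — so an error rate of 0.5 miscalls exactly half the sites in
expectation. Genotype quality is the Phred score of that majority vote's
error probability, capped at 255 as in VCF GQ. Sites inside
`het_artifact_regions` emit heterozygous ref/alt calls in every sample,
mimicking repetitive-element artifacts that are impossible genotypes in
haploids; sites inside `cnv_regions` are flagged copy-number variable.
The generator does not model alignment bias, indel realignment errors, or
contamination — so passing the oracle-equivalence tests shows the cascade
logic is correct, not that it is robust to every failure mode of real
short-read data.

## Filter cascade conventions

- Thresholds are strict (“greater than”): depth > 20, quality > 60, in all
  samples.
- A record with any missing role call is dropped at the depth/quality stage
  and logged, never raised.
- Heterozygosity in a haploid context means a call string with two different
  alleles; an optional allele-balance rule (minor-read fraction) exists but
  is off by default.
- CNV regions are BED-convention 0-based half-open; variant positions are
  VCF 1-based. The conversion lives in one function
  (`filtering.position_in_regions`). A record is CNV-dropped when flagged in
  *any* sample by default (`cnv_mode="all"` is available; the printed filter
  description is ambiguous between the readings, and any-sample is the
  conservative one).
- Status classification compares full allele strings against the *parent*
  call — the published reference genome is not the baseline. Three-way
  disagreements are INCONSISTENT; sites where the evolved strain matches the
  parent are NOT_EVOLVED_SPECIFIC.
- SNP vs indel: a record is a SNP when its reference and every alternate
  allele are single bases.

## Tetrad analysis

Genotype tetrads must satisfy 2:2 at both loci (violations raise — they are
not meiotic tetrads) and always classify as PD, TT or NPD. Linkage is an
exact two-sided binomial test of PD versus NPD (α = 0.05), chosen over
chi-square because observed counts are small (e.g. 4 vs 1). Phenotype-based
classification maps each spore's µ_max to the nearest model class with
decision boundaries at midpoints between the four class rates and an
ambiguity margin (default ±0.01 h⁻¹) around each boundary; a tetrad with any
ambiguous spore is UNCLASSIFIED. When the two single-mutant rates differ by
less than twice the margin the classifier refuses to distinguish them
(SINGLE_MERGED) and such tetrads are likewise UNCLASSIFIED rather than
guessed, even where the 2:2 constraint would in principle resolve them.

## Growth quantification

G-values convert to OD600 equivalents by the instrument calibration
OD = 6.1761·10⁻⁸ · G^3.4784. µ_max is the steepest least-squares slope of
ln OD over sliding windows of consecutive scans (scans every 40 min).
The default window is 7 points (≈4.7 h), appropriate for clean curves; the
estimator takes the maximum over many windows, which is upward-biased by
roughly the per-window slope standard error
σ_slope = σ_noise / √(Σ(t−t̄)²). At multiplicative noise σ = 0.05 a 7-point
window gives σ_slope ≈ 0.014 h⁻¹ — far above a 0.005 h⁻¹ recovery target —
while 21 points (14 h) gives ≈ 0.002 h⁻¹; recovery tests therefore fit with
`window_points=21`, and a calibration grid (µ ∈ {0.033, 0.060, 0.130},
lag ∈ {0, 10, 20} h, noise ≤ 0.05) confirms median absolute errors of
≤ 0.004 h⁻¹ (µ) and ≤ 1 h (lag) at that window. An optional 3-point median
filter is available and off by default. Lag is the classical geometric
construction — the intersection of the max-growth tangent in ln OD with the
baseline ln of the first scan (the known inoculation density) — clipped to
[0, window start]; lag is undefined (None) when µ_max = 0. Slopes below
10⁻¹² are reported as µ_max = 0 (numerically flat). Because no standard lag
definition exists, agreement with externally reported lag values is not
asserted anywhere — only internal round-trip consistency.

Simulated curves are logistic: OD(t) = od0 below the lag, then logistic
growth toward `od_cap` (defaults od0 = 0.2, the inoculation OD; cap 10;
72 h duration), log-normal multiplicative noise, then conversion to
G-values. The log-slope of a logistic never reaches µ, so the estimator is
≤ the true rate on noise-free curves and converges as od_cap → ∞.

## Enzyme assay

Net A340 slope (reaction − background, both least-squares fits) converts to
mM NADH/min via Beer–Lambert with ε = 6.22 mM⁻¹ cm⁻¹ and the cuvette path;
1 mM/min equals 1 µmol/mL/min, i.e. 1 U/mL of reaction mixture, scaled to
U/mg by the extract protein in the cuvette
(reaction_volume / (extract_volume × protein_concentration); defaults 1 mL,
10 µL, with protein from a Bradford measurement supplied by the caller).
NADH oxidation makes slopes negative; activities are reported as positive
magnitudes and traces whose net slope has the unexpected sign can be
flagged (`net_slope_is_expected_sign`), never clipped. Assay-mix
composition and temperature are metadata and do not enter the computation.

## Annotation conventions

Only coding-strand CDS coordinates are accepted; genomic→CDS projection
(strand, introns) is upstream of this package, since all loci of interest
are given in CDS coordinates. The standard nuclear genetic code is used
throughout; the single mitochondrial variant in the packaged table is
classifiable by genotype configuration but never effect-annotated.
Truncation counts the stop-replaced residue as lost
(full − (stop − 1)): a stop at residue 1283 of a 1872-residue protein
truncates 590 residues — the only convention consistent with the documented
pair. `CodingSequence` permits internal stop codons (a truncated allele is
a legitimate reference for annotating a stop-to-sense reversion, the central
event at UBR2) and exposes the first one as `premature_stop_residue`.

## Packaged data and its limits

The ten-variant trio table encodes the seven SNP rows exactly as published.
The three repeat-length indel rows preserve the published variant class,
per-strain identity pattern and status, but their precise repeat alleles are
synthetic reconstructions (the printed table concatenates them ambiguously).
The GUT1/UBR2 CDS fixtures are synthetic sequences — random sense codons
seeded for reproducibility — constructed to carry the documented codons at
the documented positions; they support the codon arithmetic and effect
calls, not sequence-level analyses. Column-to-strain assignment of the two
GUT1 positions 1597/1588 follows the documented residue pairing
(533 → PW-1, 530 → PW-2).

## Determinism and seeds

Every stochastic operation takes an explicit integer seed and is
bit-reproducible given (inputs, seed). Pipeline-level functions derive
per-stage seeds from a master seed with `numpy.random.SeedSequence(master,
spawn_key=(stage,))` (`simulate.stage_seed`), which guarantees
non-overlapping streams; derived seeds are kept below 2³¹.

## Problem sizes used in the test suite

Segregation and linkage properties use 10,000 tetrads on one- or
two-chromosome genomes; the backcross dilution uses 40 replicate programs of
300 neutral mutations each (12,000 sites) on the 16-chromosome genome;
growth recovery uses 100 seeds per grid point; the end-to-end check runs
200 replicate cohorts of 8 neutral + 2 causal mutations through the full
pipeline. These sizes keep Monte-Carlo error comfortably inside the asserted
tolerances while the whole suite completes in well under a minute.

## Known limitations

- No crossover/chromatid interference and no centromere effects; tetrad
  statistics are the far-from-centromere limit.
- The phenotype model is a deterministic two-locus lookup; biological
  growth-rate variance between genetically identical segregants is not
  modelled (it would blur phenotype-based tetrad scoring).
- The call-noise model is site-independent; linked error modes (mapping
  bias around indels, repeat expansions) are represented only by the
  explicit artifact/CNV region lists.
- Fitness models with more than two causal loci, FASTQ/read-level
  simulation, CNV *detection*, and genome-wide functional annotation are out
  of scope.
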