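# alecross

Backcross-based causal-mutation mapping for adaptively evolved haploid
yeast, as a reusable, fully testable pipeline.

## The problem

Adaptive laboratory evolution (ALE) selects spontaneous beneficial
mutations — in the motivating case, mutations that let *Saccharomyces
cerevisiae* CEN.PK strains grow on glycerol, a phenotype the wild-type
strains lack entirely. An evolved isolate carries a handful of point
mutations, only some of them causal. Backcrossing the evolved strain to its
unevolved parent while selecting segregants for the phenotype purifies the
genome: each meiosis transmits every evolved-specific heterozygous site to
a given spore with probability ½, so after *k* unselected rounds a neutral
mutation survives with probability 0.5^k (87.5 % eliminated after three
rounds), while causal mutations are retained by selection. Sequencing the
trio (parent, evolved strain, backcrossed segregant) then splits the
evolved-specific variants into *lost in backcross* (segregant carries the
parental allele) and *segregating* (segregant kept the evolved allele) —
the segregating set contains the causal candidates.

`alecross` implements every quantitative step of that design:

- **simulate** — haploid genomes with Poisson neutral mutations plus planted
  causal loci; meiosis at the four-chromatid level (Poisson crossovers,
  uniform positions, no interference, exact 2:2 segregation); multi-round
  backcross programs with phenotype-based selection; genotype calls with
  read-depth/quality noise, heterozygous repetitive-region artifacts and CNV
  flags; plate-monitor growth curves observed through the instrument's
  power-law calibration.
- **filtering** — the variant filter cascade (read depth > 20 and genotype
  quality > 60 in all samples; polymorphic within the cohort; no
  heterozygous calls; no CNV overlap) and the trio genotype-configuration
  classifier.
- **annotate** — CDS position → codon/residue arithmetic
  (codon = ⌈pos/3⌉), per-codon effect calls (missense / nonsense /
  stop-substitution) against the standard genetic code, and truncation
  lengths for premature stops.
- **tetrads** — Perkins PD/TT/NPD classification from genotypes or growth
  phenotypes, exact-binomial linkage verdicts, and the Perkins map distance
  100·(TT/2 + 3·NPD)/total.
- **growth** — G-value → OD600 conversion (OD = 6.1761·10⁻⁸ · G^3.4784),
  µ_max as the steepest sliding-window slope of ln OD, and geometric lag
  estimation.
- **assay** — specific glycerol-kinase activity (U/mg) from NADH-coupled
  A340 traces via Beer–Lambert (ε = 6.22 mM⁻¹ cm⁻¹), with background
  subtraction.

The packaged reference data (`alecross.datasets`) include the ten-variant
filtered table of the CEN.PK113-7D / JL1 / F3 trio and synthetic GUT1/UBR2
CDS fixtures carrying the documented codons at the documented positions.

## Worked example

```python
from alecross import datasets, filtering

records = datasets.trio_filtered_variants()
result = filtering.run_cascade(
    records, filtering.FilterConfig(), datasets.trio_roles()
)
print(result.summary)
```

```
{'input': 10, 'after_depth_quality': 10, 'after_polymorphic': 10,
 'after_heterozygous': 10, 'after_cnv': 10, 'n_snps': 7, 'n_indels': 3,
 'lost_in_backcross': 8, 'segregating': 2,
 'not_evolved_specific': 0, 'inconsistent': 0}
```

Ten variants (7 SNPs, 3 indels) survive the cascade; eight were lost in the
backcross and two segregate with the phenotype — the GUT1 and UBR2 coding
mutations. Codon arithmetic places them: GUT1 CDS 353 → residue 118
(Ser→Phe missense), UBR2 CDS 3848 → residue 1283, where the CEN.PK-family
premature stop (truncating 590 of 1872 residues) is replaced by tryptophan.

Tetrad counts scored during the backcrossing classify the architecture:

```python
from alecross import tetrads
print(tetrads.infer_architecture(4, 11, 1, 4).text())
```

```
Tetrads: PD=4 TT=11 NPD=1 unclassified=4 (80% classifiable)
Two-locus verdict: unlinked (exact binomial PD vs NPD, p=0.375)
Perkins map distance: 53.1 cM
```

And a simulated plate-monitor curve round-trips through the growth module:

```python
from alecross import growth, simulate
curve = simulate.simulate_growth_curve(0.130, lag=15.0, noise_sd=0.02, seed=1)
stats = growth.estimate_mu_max(curve, window_points=21)
print(f"mu_max={stats.mu_max:.4f} /h, lag={stats.lag:.2f} h, r2={stats.r_squared:.4f}")
```

```
mu_max=0.1232 /h, lag=15.01 h, r2=0.9973
```

A `click` CLI mirrors the library:
`alecross simulate genomes|cross|calls|growth`, `alecross filter`,
`alecross annotate`, `alecross tetrads`, `alecross growth`,
`alecross assay` (see `--help` on each).

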