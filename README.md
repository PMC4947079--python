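# indelpop

Forensic population genetics for biallelic insertion/deletion (InDel)
marker panels: per-locus forensic parameters, exact Hardy–Weinberg
testing, linkage-disequilibrium screening, between-population distances
and trees, PCA, and seeded genotype simulation — as a Python library and
a command-line pipeline.

The package ships a worked 30-locus case study: a 136-individual panel
summary (DIP+ allele frequency and observed heterozygosity per locus)
plus a 22-population Nei DA distance matrix, packaged as checksummed CSV
fixtures. Every published headline statistic of that panel is recomputed
from the fixture by `scripts/acceptance.py`.

## What it computes

For a biallelic locus the insertion allele is DIP+ and the deletion
allele DIP−. Genotypes are stored as insertion dose (0, 1, 2). With
genotype counts (n_II, n_ID, n_DD), n individuals and p = freq(DIP+),
q = 1 − p:

| quantity | formula |
|---|---|
| observed heterozygosity | Ho = n_ID / n |
| unbiased expected heterozygosity | He = n/(n−1) · (1 − p² − q²) |
| match probability / power of discrimination | MP = Σ genotype-proportions², PD = 1 − MP |
| polymorphic information content | PIC = 1 − (p² + q²) − 2p²q² |
| power of exclusion | PE = h²(1 − 2hH²), h = Ho, H = 1 − h |
| typical paternity index | TPI = 1 / (2(1 − Ho)) |
| combined PD / PE over a panel | CPD = 1 − Π MP, CPE = 1 − Π (1 − PE) |

Beyond the per-locus table:

- **HWE**: Levene's conditional exact test (sum of configuration
  probabilities ≤ the observed one; optional mid-p variant) with a
  Bonferroni screen across the panel.
- **LD**: EM maximum-likelihood haplotype frequencies from unphased
  two-locus genotypes and r² = D²/(p_A q_A p_B q_B); a composite
  (dosage-correlation) estimator as a cross-check.
- **Population comparison**: Nei et al. (1983) DA distance from allele
  frequencies; Weir–Cockerham θ (Fst) with a label-permutation test.
- **Trees/ordination**: Saitou–Nei neighbor joining (exact on additive
  matrices), Newick output, nearest-neighbor queries, and PCA of
  population allele-frequency tables via SVD.
- **Simulation**: seeded Hardy–Weinberg genotype draws (with optional
  inbreeding departure f), Balding–Nichols population divergence with
  target Fst, and two-locus draws at a chosen D.

## Worked example

Reconstruct genotype counts from the packaged panel summary and compute
the forensic report:

```python
from indelpop import fixture_study, panel_from_counts

freq_table, counts, da = fixture_study()
panel = panel_from_counts(counts)
print(panel.cpd_str())       # 0.99999999999940
print(round(panel.cpe, 4))   # 0.9963
print(panel.hwe_flags)       # []  (no HWE departures at 0.05/30)
```

The same pipeline from the shell, using the published per-locus
summaries (locus, dip_plus, ho, n) instead of raw genotypes:

```console
$ indelpop forensic --summaries summaries.csv --out out/
loci: 30
CPD: 0.99999999999940
CPE: 0.9963
Bonferroni level: 0.0017
HWE departures after correction: none
```

Simulate a panel and screen it for LD:

```console
$ indelpop simulate --study-preset --seed 42 --out sim/
wrote sim/genotypes.csv (136 x 30)
$ indelpop ld --genotypes sim/genotypes.csv --out ld/
435 pairs tested; 0 at r^2 >= 0.1
```

Build the NJ tree and nearest-neighbor table from a distance matrix
(square or lower-triangular CSV, or PHYLIP):

```console
$ indelpop compare --distances da_matrix.csv --out cmp/
outputs in cmp
```

Every command writes a `provenance.json` (package version, command,
parameters, seed) next to its outputs, so stochastic runs are exactly
reproducible from the recorded seed.

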