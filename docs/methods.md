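# Methods and numerical conventions

This note records the statistical definitions, defaults, and numerical
decisions behind `indelpop`, and what the simulators do and do not
emulate.

## Data model

A locus is biallelic: insertion (DIP+) and deletion (DIP−). Genotypes
are stored as insertion dose in `int8` (0 = DD, 1 = ID, 2 = II;
−1 = missing). All per-locus statistics are functions of the genotype
count triple (n_II, n_ID, n_DD); `GenotypeCounts` is therefore the
sufficient statistic passed between modules.

Three text dialects are accepted for genotype tables: `ID` (`II`, `ID`,
`DD`), `+/-` (`+/+`, `+/-`, `-/-`), and `1/0` (`1/1`, `1/0`, `0/0`).
Parsing is strict by default; lenient mode maps unparseable cells to
missing.

### Count reconstruction from published summaries

Published panel tables report the DIP+ frequency and Ho rounded to four
decimals at known n. `reconstruct_counts` inverts this: n_ID is the
integer minimizing |n_ID/n − Ho|, n_II follows from the allele count
nearest to 2n·p, and the result is accepted only if re-rounding
(half-up, 4 decimals) reproduces the printed pair exactly; otherwise a
ValueError reports the mismatch. For the packaged 30-locus table the
inversion is unique at every locus.

### Rounding

Published forensic tables round halves away from zero. Python's builtin
`round` is banker's rounding, which differs visibly at 4 decimals, so
all table-facing output uses `round4` (decimal.Decimal, ROUND_HALF_UP).
Internal computation always uses exact count-based values (e.g. Ho =
n_ID/n, not the printed rounded Ho); chaining printed values through
nonlinear formulas like TPI does not reproduce the published digits.

## Forensic parameters

With p = freq(DIP+), q = 1 − p, h = Ho = n_ID/n, H = 1 − h:

- He (unbiased) = n/(n−1) · (1 − p² − q²)
- MP = Σ over the three genotype classes of (count/n)²; PD = 1 − MP.
  MP uses **observed** genotype proportions, not HWE expectations.
- PIC = 1 − (p² + q²) − 2p²q²
- PE = h²(1 − 2hH²)
- TPI = 1/(2(1 − Ho)); undefined (error) at Ho = 1
- CPD = 1 − Π MP_l; CPE = 1 − Π (1 − PE_l). CPD is close enough to 1
  that `PanelForensics.cpd_str(digits=14)` formats it from the product
  of MPs directly to avoid printing 1.0.

## Hardy–Weinberg exact test

Levene's conditional distribution: given n and the allele count
n_A = 2n_II + n_ID, the probability of n_ID heterozygotes is

P(n_ID | n, n_A) = n! / (n_II! n_ID! n_DD!) · 2^{n_ID} · n_A!(2n−n_A)! / (2n)!

computed in log space with `math.lgamma`. The two-sided p-value sums
P over all configurations with probability ≤ the observed one (the
convention of Weir and of common exact-test software). When every
configuration is included, the p-value is returned as exactly 1.0. The
mid-p variant (half weight on configurations with probability equal to
the observed) is available behind `midp=True` but is not the default.
The panel screen uses Bonferroni: threshold α/L (0.05/30 = 0.0017 for
the packaged panel).

The packaged fixture retains the study's published per-locus HWE
p-values as data. Those published values do not equal any deterministic
exact-test variant (they came from an MCMC approximation); the package
computes the exact values instead, and the panel-level conclusion (no
locus significant after Bonferroni correction) is identical.

## Linkage disequilibrium

For a locus pair, unphased genotypes are tallied into a 3×3 dose table.
Haplotype frequencies are estimated by EM: all classes except the
double heterozygote have fixed haplotype counts; the double
heterozygote's two phase resolutions are split proportionally to the
current estimates each iteration. Initialization is linkage
equilibrium; convergence tolerance 1e-10 on frequencies, cap 1000
iterations; the log-likelihood trace is kept and is non-decreasing.
Then r² = D²/(p_A q_A p_B q_B) with D = f_II − p_A p_B. r² is undefined
(error) if either locus is monomorphic; `pairwise_ld` skips such loci
with a warning and stores NaN. A composite estimator (squared Pearson
correlation of allele dosages) is provided as a phase-free cross-check;
under HWE the two agree closely.

Null behavior worth knowing: for unphased genotype data the sampling
scale of r̂ is 1/√n (not 1/√(2n) as for phased haplotypes), so under
independence E[r̂²] ≈ 1/n and a single pair exceeds the conventional
0.1 screen at n = 136 with probability ≈ 2·10⁻⁴. Over a 435-pair panel
roughly 8% of fully independent replicates still show at least one pair
above 0.1.

## Population comparison

- Nei et al. (1983) DA for biallelic loci:
  DA = 1 − (1/L) Σ_l (√(x_+ y_+) + √(x_− y_−)).
- Weir–Cockerham θ: the a (among-population), b (among-individual) and
  c (within-individual) variance components are computed per locus for
  two populations and summed across loci before forming θ = Σa/Σ(a+b+c)
  (ratio of sums, not mean of ratios). Monomorphic loci contribute
  nothing and trigger a warning. Significance is by permutation of
  individuals across population labels; p = (b + 1)/(m + 1) where b is
  the number of permuted θ ≥ observed. `locuswise_differentiation`
  counts loci with per-locus permutation p below a level (default
  0.05).
- Distance matrices are read/written as labeled square CSV, square
  PHYLIP, or lower-triangular in either format; lower triangles are
  mirrored, and square inputs must be symmetric to 1e-9, zero-diagonal,
  and non-negative.

## Trees and ordination

Neighbor joining follows Saitou–Nei with the Studier–Keppler Q
criterion. Ties in Q are broken by the lowest (row, column) index pair,
which makes output deterministic and label-order dependent only through
ties. Negative branch lengths are clamped to zero with the deficit
transferred to the sister branch, preserving path lengths where
possible; on additive matrices the algorithm recovers the generating
tree exactly (tested by property). Topology comparisons use canonical
split sets: each internal edge is represented by the smaller side
(ties by sorted labels). Newick output quotes labels containing
non-alphanumeric characters.

PCA operates on the population × locus DIP+ frequency matrix: columns
are centered (no variance scaling — frequencies share a scale), scores
come from the SVD, and each component's sign is fixed by making its
largest-magnitude loading positive. Explained-variance ratios equal the
eigendecomposition of the covariance to 1e-8 (tested against an
independent oracle).

## Simulators

- `simulate_genotypes`: per-locus genotype probabilities
  (p² + fpq, 2pq(1−f), q² + fpq) with inbreeding-style departure f;
  f is validated against its feasibility bound −min(p/q, q/p) ≤ f ≤ 1.
- `simulate_populations_bn`: Balding–Nichols — each population's locus
  frequency is Beta(p(1−F)/F, (1−p)(1−F)/F), so F equals the expected
  Fst; genotypes are then drawn under HWE within each population.
- `simulate_ld_pair`: diplotypes as pairs of haplotypes drawn from
  frequencies (p_A p_B + D, …); D is validated against the Lewontin
  bounds and the admissible interval is reported on error.

Randomness: a mandatory integer seed feeds `numpy.random.SeedSequence`;
each locus gets its own spawned substream, so extending a panel with
additional loci never changes earlier loci's draws, and all derived
seeds are reduced modulo 2³¹. The simulators emulate sampling from
idealized panmictic (or F-divergent) populations only — no mutation,
genuine physical linkage, genotyping error, or missingness processes.

## Packaged fixtures

Two CSVs ship inside the package (≈3–4 KB each): the 30-locus panel
summary (locus, rs id, cytoband, allele frequencies, forensic
parameters, n = 136) and a 22-population DA matrix. Both are verified
against SHA-256 checksums on load; tampering raises ValueError. The
fixture loaders return live objects (FreqTable, reconstructed
GenotypeCounts, DistanceMatrix) so downstream code never re-parses the
CSVs.

## Limitations

- The exact HWE test is O(n_A) per locus — fine for forensic panel
  sizes, untested beyond n ≈ 10⁵.
- Weir–Cockerham θ is implemented for two populations (the permutation
  design the CLI exposes); multi-population θ is out of scope.
- EM LD assumes HWE at both loci for phase resolution; strong HWE
  departure biases r².
- PCA percentages for multi-population studies depend entirely on which
  reference frequency tables are supplied; none are bundled beyond the
  distance-matrix fixture.
- The NJ tie-break and negative-branch policy are conventions; other
  software may emit different (equally valid) resolutions for tied or
  non-additive inputs.
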