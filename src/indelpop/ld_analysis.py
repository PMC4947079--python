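"""Pairwise linkage disequilibrium (r^2) between biallelic loci.

Unphased diploid genotypes at two biallelic loci reduce to a 3x3 table of
two-locus genotype counts.  Every cell except the double heterozygote has a
known haplotype decomposition; the double heterozygote mixes the coupling
(II/DD) and repulsion (ID/DI) phases.  Haplotype frequencies are estimated
by expectation-maximization over that single ambiguity, and

    D   = f_II - pA * pB
    r^2 = D^2 / (pA qA pB qB)

is the squared allelic correlation.  A composite (Burrows) estimator that
needs no phase resolution is provided as a cross-check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .genotype_model import GenotypeMatrix, MISSING

__all__ = [
    "HaplotypeFreqs",
    "LDMatrix",
    "two_locus_counts",
    "em_haplotype_freqs",
    "r_squared",
    "composite_r_squared",
    "pairwise_ld",
]


@dataclass
class HaplotypeFreqs:
    """Frequencies of the four two-locus haplotypes (I/D at locus A, B)."""

    f_ii: float
    f_id: float
    f_di: float
    f_dd: float
    converged: bool = True
    n_iter: int = 0
    loglik_trace: list[float] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        f = (self.f_ii, self.f_id, self.f_di, self.f_dd)
        if min(f) < -1e-12:
            raise ValueError("negative haplotype frequency")
        if abs(sum(f) - 1.0) > 1e-9:
            raise ValueError("haplotype frequencies must sum to 1")

    @property
    def p_a(self) -> float:
        """Insertion-allele frequency at the first locus."""
        return self.f_ii + self.f_id

    @property
    def p_b(self) -> float:
        """Insertion-allele frequency at the second locus."""
        return self.f_ii + self.f_di

    @property
    def d(self) -> float:
        """Linkage-disequilibrium coefficient D = f_II - pA pB."""
        return self.f_ii - self.p_a * self.p_b


@dataclass
class LDMatrix:
    loci: list[str]
    r2: np.ndarray

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, dtype=float)
        k = len(self.loci)
        if self.r2.shape != (k, k):
            raise ValueError("r2 matrix shape inconsistent with locus list")
        if not np.allclose(self.r2, self.r2.T, equal_nan=True):
            raise ValueError("r2 matrix must be symmetric")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r2, index=self.loci, columns=self.loci)

    def to_long(self, threshold: float | None = None) -> pd.DataFrame:
        rows = []
        for i, j in combinations(range(len(self.loci)), 2):
            v = self.r2[i, j]
            row = {"locus_a": self.loci[i], "locus_b": self.loci[j], "r2": v}
            if threshold is not None:
                row["flagged"] = bool(v >= threshold)
            rows.append(row)
        return pd.DataFrame(rows)


def two_locus_counts(gm: GenotypeMatrix, locus_a, locus_b) -> np.ndarray:
    """3x3 tally of joint genotypes; axes indexed by insertion-allele dose."""
    a = gm.calls[:, gm.locus_index(locus_a)]
    b = gm.calls[:, gm.locus_index(locus_b)]
    keep = (a != MISSING) & (b != MISSING)
    counts = np.zeros((3, 3), dtype=int)
    np.add.at(counts, (a[keep].astype(int), b[keep].astype(int)), 1)
    return counts


def _complete_loglik(counts: np.ndarray, f: np.ndarray) -> float:
    """Observed-data log-likelihood of the 3x3 genotype table under f."""
    f_ii, f_id, f_di, f_dd = f
    # genotype probability of cell (i, j), i = dose at A, j = dose at B
    g = np.empty((3, 3))
    g[2, 2] = f_ii ** 2
    g[2, 1] = 2 * f_ii * f_id
    g[2, 0] = f_id ** 2
    g[1, 2] = 2 * f_ii * f_di
    g[1, 1] = 2 * f_ii * f_dd + 2 * f_id * f_di
    g[1, 0] = 2 * f_id * f_dd
    g[0, 2] = f_di ** 2
    g[0, 1] = 2 * f_di * f_dd
    g[0, 0] = f_dd ** 2
    mask = counts > 0
    with np.errstate(divide="ignore"):
        lg = np.log(np.where(g > 0, g, 1.0))
    if np.any(mask & (g == 0)):
        return -np.inf
    return float((counts * lg)[mask].sum())


def em_haplotype_freqs(counts: np.ndarray, tol: float = 1e-10,
                       max_iter: int = 1000) -> HaplotypeFreqs:
    """Maximum-likelihood haplotype frequencies from a 3x3 genotype tally.

    The EM iteration splits the double-heterozygote count between coupling
    and repulsion phases in proportion to the current estimates; every other
    cell contributes fixed haplotype counts.  Initialization is at linkage
    equilibrium (product of the marginal allele frequencies), where the
    biallelic two-locus likelihood has no spurious optima of practical
    concern.  Convergence: max absolute frequency change below ``tol``.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.shape != (3, 3):
        raise ValueError("expected a 3x3 two-locus genotype tally")
    n = counts.sum()
    if n <= 0:
        raise ValueError("empty two-locus tally")
    doses_a = counts.sum(axis=1) @ np.array([0, 1, 2])
    doses_b = counts.sum(axis=0) @ np.array([0, 1, 2])
    p_a = doses_a / (2 * n)
    p_b = doses_b / (2 * n)

    # fixed haplotype contributions from the 8 unambiguous cells:
    # cell (i, j) with i+j != 2 or |i-j| == 2 is phase-known
    def fixed_hap_counts() -> np.ndarray:
        h = np.zeros(4)  # ii, id, di, dd
        for i in range(3):
            for j in range(3):
                c = counts[i, j]
                if c == 0 or (i == 1 and j == 1):
                    continue
                n_i_a, n_d_a = i, 2 - i
                n_i_b, n_d_b = j, 2 - j
                # phase-known: haplotypes are determined by the doses
                h[0] += c * min(n_i_a, n_i_b)
                h[3] += c * min(n_d_a, n_d_b)
                rem_a = n_i_a - min(n_i_a, n_i_b)
                rem_b = n_i_b - min(n_i_a, n_i_b)
                h[1] += c * rem_a  # I at A paired with D at B
                h[2] += c * rem_b
        return h

    base = fixed_hap_counts()
    dbl = counts[1, 1]
    f = np.array([p_a * p_b, p_a * (1 - p_b), (1 - p_a) * p_b,
                  (1 - p_a) * (1 - p_b)])
    trace = [_complete_loglik(counts.astype(int), f)]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        coupling = f[0] * f[3]
        repulsion = f[1] * f[2]
        tot = coupling + repulsion
        w = 0.5 if tot == 0 else coupling / tot
        h = base.copy()
        h[0] += dbl * w
        h[3] += dbl * w
        h[1] += dbl * (1 - w)
        h[2] += dbl * (1 - w)
        f_new = h / (2 * n)
        delta = np.abs(f_new - f).max()
        f = f_new
        trace.append(_complete_loglik(counts.astype(int), f))
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"EM did not converge in {it} iterations", stacklevel=2)
    f = np.clip(f, 0.0, 1.0)
    f = f / f.sum()
    return HaplotypeFreqs(*f, converged=converged, n_iter=it,
                          loglik_trace=trace)


def r_squared(hf: HaplotypeFreqs) -> float:
    """Squared allelic correlation r^2 = D^2 / (pA qA pB qB)."""
    pa, pb = hf.p_a, hf.p_b
    denom = pa * (1 - pa) * pb * (1 - pb)
    if denom <= 0:
        raise ValueError("r^2 undefined: monomorphic locus")
    return min(1.0, hf.d ** 2 / denom)


def composite_r_squared(counts: np.ndarray) -> float:
    """Composite (genotypic) r^2: squared dosage correlation, no phasing.

    The squared Pearson correlation between insertion-allele dosages at the
    two loci.  Needs no phase resolution and equals the haplotypic r^2 under
    Hardy-Weinberg proportions; serves as a model-free cross-check on the
    EM estimate.
    """
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    if n <= 0:
        raise ValueError("empty two-locus tally")
    i = np.arange(3.0)
    mean_a = (counts.sum(axis=1) @ i) / n
    mean_b = (counts.sum(axis=0) @ i) / n
    var_a = (counts.sum(axis=1) @ i ** 2) / n - mean_a ** 2
    var_b = (counts.sum(axis=0) @ i ** 2) / n - mean_b ** 2
    if var_a <= 0 or var_b <= 0:
        raise ValueError("r^2 undefined: monomorphic locus")
    cov = (counts * np.outer(i, i)).sum() / n - mean_a * mean_b
    return min(1.0, cov ** 2 / (var_a * var_b))


def pairwise_ld(gm: GenotypeMatrix, threshold: float = 0.1,
                method: str = "em") -> tuple[LDMatrix, list[tuple[str, str]]]:
    """r^2 for every unordered locus pair; pairs at or above the threshold.

    Monomorphic loci are skipped (their r^2 cells are NaN) with a warning.
    """
    if len(gm.loci) < 2:
        raise ValueError("need at least 2 loci for pairwise LD")
    if method not in ("em", "composite"):
        raise ValueError("method must be 'em' or 'composite'")
    k = len(gm.loci)
    r2 = np.full((k, k), np.nan)
    np.fill_diagonal(r2, 1.0)
    poly = []
    for j in range(k):
        col = gm.calls[:, j]
        typed = col[col != MISSING]
        if typed.size and 0 < typed.sum() < 2 * typed.size:
            poly.append(j)
        else:
            warnings.warn(
                f"locus {gm.locus_ids[j]!r} is monomorphic; skipped in LD scan",
                stacklevel=2,
            )
    flagged = []
    for a, b in combinations(poly, 2):
        counts = two_locus_counts(gm, gm.loci[a], gm.loci[b])
        if method == "em":
            val = r_squared(em_haplotype_freqs(counts))
        else:
            val = composite_r_squared(counts)
        r2[a, b] = r2[b, a] = val
        if val >= threshold:
            flagged.append((gm.locus_ids[a], gm.locus_ids[b]))
    return LDMatrix(gm.locus_ids, r2), flagged
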