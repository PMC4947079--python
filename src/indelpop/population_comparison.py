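"""Between-population statistics: Nei's DA distance and Weir-Cockerham Fst.

DA (Nei, Tajima & Tateno 1983) is computed from allele-frequency tables:

    DA = 1 - (1/L) * sum_loci sum_alleles sqrt(x_a * y_a)

with the two InDel alleles {I, D} per locus.  It is the distance used by
forensic population surveys to compare a studied group with published
reference groups, for which only frequency tables exist.

Fst is the Weir & Cockerham (1984) theta moment estimator computed from
genotype matrices, with variance components summed across loci before the
ratio, and a permutation test that shuffles individuals between the two
populations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .genotype_model import FreqTable, GenotypeMatrix, MISSING

__all__ = [
    "DistanceMatrix",
    "FstResult",
    "nei_da",
    "da_matrix",
    "wc_fst",
    "locuswise_differentiation",
    "read_distance_matrix",
    "write_distance_matrix",
]


@dataclass
class DistanceMatrix:
    """Labeled symmetric non-negative distance matrix with zero diagonal."""

    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        k = len(self.labels)
        if self.d.shape != (k, k):
            raise ValueError("matrix shape inconsistent with label count")
        if len(set(self.labels)) != k:
            raise ValueError("duplicate labels")
        if not np.allclose(self.d, self.d.T, atol=1e-9):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(self.d < 0):
            raise ValueError("distances must be non-negative")
        # exact symmetry after the tolerance check
        self.d = (self.d + self.d.T) / 2.0

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.d[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.labels, columns=self.labels)


@dataclass
class FstResult:
    """Pairwise Weir-Cockerham theta with permutation p-values."""

    theta: float
    perm_p: float
    per_locus_theta: np.ndarray
    per_locus_p: np.ndarray
    loci: list[str]
    n_perm: int


def nei_da(x: np.ndarray, y: np.ndarray) -> float:
    """Nei et al. DA distance between two insertion-frequency rows."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size == 0:
        raise ValueError("frequency rows must be 1-D, same locus set, non-empty")
    for arr in (x, y):
        if np.any((arr < 0) | (arr > 1)):
            raise ValueError("frequencies must lie in [0, 1]")
    shared = np.sqrt(x * y) + np.sqrt((1 - x) * (1 - y))
    return float(1.0 - shared.mean())


def da_matrix(ft: FreqTable) -> DistanceMatrix:
    """All pairwise DA distances for the populations of a frequency table."""
    if len(ft.populations) < 2:
        raise ValueError("need at least 2 populations")
    p = ft.p_ins_matrix()
    k = p.shape[0]
    d = np.zeros((k, k))
    for i, j in combinations(range(k), 2):
        try:
            d[i, j] = d[j, i] = nei_da(p[i], p[j])
        except ValueError as e:
            raise ValueError(
                f"DA({ft.populations[i]!r}, {ft.populations[j]!r}): {e}"
            ) from e
    return DistanceMatrix(list(ft.populations), d)


# ---------------------------------------------------------------------------
# Weir-Cockerham theta
# ---------------------------------------------------------------------------

def _wc_components(calls: np.ndarray, labels: np.ndarray):
    """Per-locus WC variance components (a, b, c) for two populations.

    ``calls``: pooled (n_individuals, L) dosage matrix with -1 missing;
    ``labels``: 0/1 population assignment per individual.  Vectorized over
    loci; loci with no typed individuals in either population get zero
    components.
    """
    r = 2.0
    comps = []
    for g in (0, 1):
        sub = calls[labels == g]
        typed = sub != MISSING
        n_i = typed.sum(axis=0).astype(float)            # (L,)
        with np.errstate(invalid="ignore", divide="ignore"):
            p_i = np.where(n_i > 0,
                           np.where(typed, sub, 0).sum(axis=0) / (2 * n_i), 0.0)
            h_i = np.where(n_i > 0,
                           ((sub == 1) & typed).sum(axis=0) / np.maximum(n_i, 1),
                           0.0)
        comps.append((n_i, p_i, h_i))
    (n1, p1, h1), (n2, p2, h2) = comps
    valid = (n1 > 0) & (n2 > 0)
    n_bar = (n1 + n2) / r
    with np.errstate(invalid="ignore", divide="ignore"):
        n_c = (r * n_bar - (n1 ** 2 + n2 ** 2) / (r * n_bar)) / (r - 1)
        p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
        s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1) * n_bar)
        h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)
        a = (n_bar / n_c) * (
            s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4)
            / (n_bar - 1)
        )
        b = (n_bar / (n_bar - 1)) * (
            p_bar * (1 - p_bar) - (r - 1) / r * s2
            - (2 * n_bar - 1) / (4 * n_bar) * h_bar
        )
        c = h_bar / 2
    for arr in (a, b, c):
        arr[~valid] = 0.0
        np.nan_to_num(arr, copy=False)
    return a, b, c


def _theta(a: np.ndarray, b: np.ndarray, c: np.ndarray):
    denom = (a + b + c).sum()
    multi = a.sum() / denom if denom != 0 else 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        per = np.where(a + b + c != 0, a / (a + b + c), np.nan)
    return multi, per


def wc_fst(pop_a: GenotypeMatrix, pop_b: GenotypeMatrix,
           n_perm: int = 10_000, seed: int | None = None) -> FstResult:
    """Pairwise Weir-Cockerham theta with a permutation test.

    The multi-locus estimate sums the (a, b, c) variance components across
    loci before taking the ratio.  Significance is assessed by shuffling
    individuals between the two samples ``n_perm`` times; p-values use the
    (b + 1)/(m + 1) correction so they are never exactly zero.  Loci
    monomorphic in both populations contribute zero components (warned).
    """
    if pop_a.locus_ids != pop_b.locus_ids:
        missing = sorted(set(pop_a.locus_ids) ^ set(pop_b.locus_ids))
        raise ValueError(f"locus panels differ between populations: {missing}")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    calls = np.vstack([pop_a.calls, pop_b.calls]).astype(np.int8)
    labels = np.concatenate([
        np.zeros(pop_a.n_individuals, dtype=int),
        np.ones(pop_b.n_individuals, dtype=int),
    ])
    pooled = np.where(calls != MISSING, calls, 0).sum(axis=0)
    typed = (calls != MISSING).sum(axis=0)
    mono = (pooled == 0) | (pooled == 2 * typed)
    if mono.any():
        names = [pop_a.locus_ids[j] for j in np.flatnonzero(mono)]
        warnings.warn(
            f"loci monomorphic across both populations contribute zero "
            f"variance components: {names}", stacklevel=2,
        )
    a, b, c = _wc_components(calls, labels)
    theta, per_theta = _theta(a, b, c)
    rng = np.random.default_rng(seed)
    ge_multi = 0
    ge_locus = np.zeros(len(pop_a.loci), dtype=int)
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        pa, pb, pc = _wc_components(calls, perm)
        t, pt = _theta(pa, pb, pc)
        if t >= theta:
            ge_multi += 1
        with np.errstate(invalid="ignore"):
            ge_locus += np.where(np.isnan(pt) | np.isnan(per_theta), 0,
                                 pt >= per_theta)
    perm_p = (ge_multi + 1) / (n_perm + 1)
    per_p = (ge_locus + 1) / (n_perm + 1)
    per_p = np.where(np.isnan(per_theta), np.nan, per_p)
    return FstResult(theta=float(theta), perm_p=float(perm_p),
                     per_locus_theta=per_theta, per_locus_p=per_p,
                     loci=list(pop_a.locus_ids), n_perm=n_perm)


def locuswise_differentiation(res: FstResult, level: float = 0.05) -> int:
    """Number of loci whose permutation p-value falls below ``level``."""
    p = res.per_locus_p
    if p is None or len(p) == 0:
        raise ValueError("per-locus p-values missing")
    return int(np.nansum(np.asarray(p) < level))


# ---------------------------------------------------------------------------
# distance matrix I/O
# ---------------------------------------------------------------------------

def write_distance_matrix(dm: DistanceMatrix, sink, format: str = "csv",
                          precision: int = 17) -> None:
    """Write a labeled distance matrix as square CSV or PHYLIP."""
    if format == "csv":
        dm.to_frame().to_csv(sink, float_format=f"%.{precision}g")
    elif format == "phylip":
        lines = [f"{len(dm.labels)}"]
        for lab, row in zip(dm.labels, dm.d):
            name = lab.replace(" ", "_")
            vals = " ".join(f"{v:.{precision}g}" for v in row)
            lines.append(f"{name}  {vals}")
        text = "\n".join(lines) + "\n"
        if hasattr(sink, "write"):
            sink.write(text)
        else:
            Path(sink).write_text(text)
    else:
        raise ValueError("format must be 'csv' or 'phylip'")


def read_distance_matrix(source, format: str = "csv") -> DistanceMatrix:
    """Read a labeled square or lower-triangular distance matrix.

    CSV: first column holds labels, header holds labels; empty upper cells
    mark a lower-triangular layout, which is mirrored on load.  PHYLIP:
    taxon count line, then one labeled row per taxon (square, or
    lower-triangular with i values in row i).  Asymmetry beyond 1e-9 in a
    square input is an error.
    """
    if format == "csv":
        df = pd.read_csv(source, index_col=0)
        labels = [str(x) for x in df.index]
        if [str(c) for c in df.columns] != labels:
            raise ValueError("row and column labels differ")
        m = df.to_numpy(dtype=float)
    elif format == "phylip":
        text = source.read() if hasattr(source, "read") else Path(source).read_text()
        lines = [l for l in text.splitlines() if l.strip()]
        k = int(lines[0].split()[0])
        if len(lines) != k + 1:
            raise ValueError(f"expected {k} taxon rows, found {len(lines) - 1}")
        labels, rows = [], []
        for i, line in enumerate(lines[1:]):
            parts = line.split()
            labels.append(parts[0].replace("_", " "))
            vals = [float(v) for v in parts[1:]]
            if len(vals) not in (k, i):
                raise ValueError(
                    f"row {parts[0]!r}: expected {k} (square) or {i} "
                    f"(lower-triangular) values, found {len(vals)}"
                )
            rows.append(vals)
        if all(len(r) == k for r in rows):
            m = np.array(rows)
        else:
            m = np.full((k, k), np.nan)
            np.fill_diagonal(m, 0.0)
            for i, vals in enumerate(rows):
                m[i, :i] = vals
    else:
        raise ValueError("format must be 'csv' or 'phylip'")

    if np.isnan(m).any():
        # lower-triangular input: mirror across the diagonal
        lower = np.tril_indices_from(m, k=-1)
        if np.isnan(m[lower]).any():
            raise ValueError("incomplete lower triangle")
        m = np.tril(np.nan_to_num(m), k=-1)
        m = m + m.T
    elif not np.allclose(m, m.T, atol=1e-9):
        raise ValueError("square distance matrix asymmetric beyond 1e-9")
    return DistanceMatrix(labels, m)
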