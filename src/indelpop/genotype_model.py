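"""Data model and I/O for biallelic insertion/deletion (InDel) genotypes.

An InDel (DIP) marker has exactly two alleles: the long insertion allele
(DIP+, coded ``I``) and the short deletion allele (DIP-, coded ``D``).  A
diploid call is therefore one of the three unordered genotypes II, ID or DD,
and the complete information a locus carries about a sample is the genotype
count triple ``(n_II, n_ID, n_DD)`` — the sufficient statistic every
downstream computation consumes.

The module also inverts the summaries forensic population reports publish
(insertion-allele frequency, observed heterozygosity, sample size) back into
that count triple, so that a printed allele-frequency table is as usable as
raw genotypes.
"""

from __future__ import annotations

import io
import re
import warnings
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LocusDef",
    "GenotypeMatrix",
    "GenotypeCounts",
    "AlleleFrequency",
    "FreqTable",
    "DIALECTS",
    "round4",
    "read_genotype_table",
    "write_genotype_table",
    "count_genotypes",
    "estimate_allele_freqs",
    "reconstruct_counts",
    "read_freq_table",
    "write_freq_table",
]

# Internal allele alphabet is fixed to {I, D}; external encodings are mapped
# at the parse/write boundary only.
DIALECTS: dict[str, dict[str, str]] = {
    "ID": {"I": "I", "D": "D"},
    "+/-": {"+": "I", "-": "D", "−": "D"},  # accept unicode minus
    "1/0": {"1": "I", "0": "D"},
}

_CYTOBAND_RE = re.compile(r"^(?:[1-9]|1[0-9]|2[0-2])[pq][\d.]*$")

# genotype codes in GenotypeMatrix.calls = number of insertion alleles
MISSING = -1


def round4(x: float) -> float:
    """Round half-up to 4 decimals, the convention of forensic report tables.

    Python's built-in ``round`` is banker's rounding; published tables round
    halves away from zero, and the difference is visible at 4 decimals.
    """
    return float(Decimal(repr(float(x))).quantize(Decimal("0.0001"),
                                                  rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class LocusDef:
    """Identity and genomic annotation of one InDel marker."""

    locus_id: str
    rs_id: int | None = None
    cytoband: str | None = None
    long_allele: str = "DIP+"
    short_allele: str = "DIP-"

    def __post_init__(self) -> None:
        if not self.locus_id:
            raise ValueError("locus_id must be non-empty")
        if self.cytoband is not None and not _CYTOBAND_RE.match(self.cytoband):
            raise ValueError(
                f"{self.locus_id}: cytoband {self.cytoband!r} is not an "
                "autosomal band (chromosome 1-22, arm p/q, band digits)"
            )


@dataclass(frozen=True)
class GenotypeCounts:
    """Per-locus diploid genotype tallies: the sufficient statistic."""

    locus_id: str
    n_ii: int
    n_id: int
    n_dd: int

    def __post_init__(self) -> None:
        if min(self.n_ii, self.n_id, self.n_dd) < 0:
            raise ValueError(f"{self.locus_id}: negative genotype count")
        if self.n == 0:
            raise ValueError(f"{self.locus_id}: no typed individuals")

    @property
    def n(self) -> int:
        return self.n_ii + self.n_id + self.n_dd

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.n_ii, self.n_id, self.n_dd)


@dataclass(frozen=True)
class AlleleFrequency:
    """Frequencies of the insertion (DIP+) and deletion (DIP-) alleles."""

    p_ins: float
    p_del: float

    def __post_init__(self) -> None:
        for v in (self.p_ins, self.p_del):
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"allele frequency {v} outside [0, 1]")
        if abs(self.p_ins + self.p_del - 1.0) > 1e-9:
            raise ValueError("p_ins + p_del must equal 1")

    @classmethod
    def of_ins(cls, p_ins: float) -> "AlleleFrequency":
        return cls(p_ins, 1.0 - p_ins)


class GenotypeMatrix:
    """Diploid genotype calls for a sample of individuals at a locus panel.

    ``calls`` is an ``(n_individuals, n_loci)`` int8 array holding the number
    of insertion alleles per call (0, 1, 2) or -1 for missing.
    """

    def __init__(self, individuals: Sequence[str], loci: Sequence[LocusDef],
                 calls: np.ndarray):
        individuals = list(individuals)
        loci = list(loci)
        calls = np.asarray(calls, dtype=np.int8)
        if calls.shape != (len(individuals), len(loci)):
            raise ValueError(
                f"calls shape {calls.shape} inconsistent with "
                f"{len(individuals)} individuals x {len(loci)} loci"
            )
        if len(set(individuals)) != len(individuals):
            raise ValueError("duplicate sample IDs")
        ids = [l.locus_id for l in loci]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate locus IDs")
        bad = ~np.isin(calls, (MISSING, 0, 1, 2))
        if bad.any():
            raise ValueError("genotype codes must be in {-1, 0, 1, 2}")
        self.individuals = individuals
        self.loci = loci
        self.calls = calls

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def locus_ids(self) -> list[str]:
        return [l.locus_id for l in self.loci]

    def locus_index(self, locus: LocusDef | str) -> int:
        lid = locus.locus_id if isinstance(locus, LocusDef) else locus
        try:
            return self.locus_ids.index(lid)
        except ValueError:
            raise KeyError(f"locus {lid!r} not in panel") from None

    def missing_per_locus(self) -> dict[str, int]:
        return {
            lid: int((self.calls[:, j] == MISSING).sum())
            for j, lid in enumerate(self.locus_ids)
        }

    def subset_loci(self, locus_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.locus_index(l) for l in locus_ids]
        return GenotypeMatrix(self.individuals,
                              [self.loci[j] for j in idx],
                              self.calls[:, idx])

    def __eq__(self, other: object) -> bool:
        return (isinstance(other, GenotypeMatrix)
                and self.individuals == other.individuals
                and self.locus_ids == other.locus_ids
                and np.array_equal(self.calls, other.calls))


@dataclass
class FreqTable:
    """Population x locus insertion-allele frequencies with sample sizes."""

    populations: list[str]
    sample_sizes: list[int]
    loci: list[str]
    # freqs[i][j] = AlleleFrequency of population i at locus j
    freqs: list[list[AlleleFrequency]] = field(repr=False)

    def __post_init__(self) -> None:
        if len(self.populations) != len(self.sample_sizes):
            raise ValueError("one sample size per population required")
        if len(set(self.populations)) != len(self.populations):
            raise ValueError("duplicate population labels")
        for n in self.sample_sizes:
            if not (isinstance(n, (int, np.integer)) and n > 0):
                raise ValueError(f"sample size {n!r} must be a positive integer")
        for pop, row in zip(self.populations, self.freqs):
            if len(row) != len(self.loci):
                raise ValueError(f"population {pop!r}: incomplete frequency row")

    def p_ins_matrix(self) -> np.ndarray:
        """(n_populations, n_loci) array of DIP+ frequencies."""
        return np.array([[af.p_ins for af in row] for row in self.freqs])

    def row(self, population: str) -> np.ndarray:
        try:
            i = self.populations.index(population)
        except ValueError:
            raise KeyError(f"population {population!r} not in table") from None
        return np.array([af.p_ins for af in self.freqs[i]])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.p_ins_matrix(), index=self.populations,
                          columns=self.loci)
        df.insert(0, "n", self.sample_sizes)
        df.index.name = "population"
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FreqTable":
        loci = [c for c in df.columns if c != "n"]
        freqs = []
        for pop, row in df.iterrows():
            r = []
            for lid in loci:
                v = float(row[lid])
                if not (0.0 <= v <= 1.0):
                    raise ValueError(
                        f"population {pop!r}, locus {lid!r}: frequency {v} "
                        "outside [0, 1]"
                    )
                r.append(AlleleFrequency.of_ins(v))
            freqs.append(r)
        return cls(populations=[str(p) for p in df.index],
                   sample_sizes=[int(v) for v in df["n"]],
                   loci=loci, freqs=freqs)


# ---------------------------------------------------------------------------
# genotype table I/O
# ---------------------------------------------------------------------------

_SEPARATORS = {".csv": ",", ".tsv": "\t", ".txt": "\t"}


def _resolve_sep(source, sep: str | None) -> str:
    if sep is not None:
        return sep
    if isinstance(source, (str, Path)):
        return _SEPARATORS.get(Path(source).suffix.lower(), ",")
    return ","


def read_genotype_table(source, dialect: str = "ID", sep: str | None = None,
                        strict: bool = False) -> GenotypeMatrix:
    """Read a genotype table: first column sample ID, one column per locus.

    Cells hold unordered allele pairs ``A1/A2`` in the given dialect
    (``"ID"``, ``"+/-"`` or ``"1/0"``).  In lenient mode unparseable cells
    become missing calls and the total is reported via a warning; in strict
    mode the first bad cell raises with its row/column coordinates.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; choose from {sorted(DIALECTS)}")
    mapping = DIALECTS[dialect]
    sep = _resolve_sep(source, sep)
    df = pd.read_csv(source, sep=sep, dtype=str)
    if df.empty or df.shape[1] < 2:
        raise ValueError("empty genotype table: need a sample column and >=1 locus")
    sample_col = df.columns[0]
    individuals = df[sample_col].tolist()
    if len(set(individuals)) != len(individuals):
        dups = sorted({s for s in individuals if individuals.count(s) > 1})
        raise ValueError(f"duplicate sample IDs: {dups}")
    loci = [LocusDef(locus_id=c) for c in df.columns[1:]]
    calls = np.full((len(individuals), len(loci)), MISSING, dtype=np.int8)
    n_bad = 0
    for j, col in enumerate(df.columns[1:]):
        for i, cell in enumerate(df[col]):
            code = _parse_call(cell, mapping)
            if code is None:
                if strict and not _is_na(cell):
                    raise ValueError(
                        f"unparseable genotype {cell!r} at sample "
                        f"{individuals[i]!r} (row {i + 2}), locus {col!r}"
                    )
                if not _is_na(cell):
                    n_bad += 1
            else:
                calls[i, j] = code
    if n_bad:
        warnings.warn(f"{n_bad} unparseable genotype cells set to missing",
                      stacklevel=2)
    return GenotypeMatrix(individuals, loci, calls)


def _is_na(cell) -> bool:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)):
        return True
    return isinstance(cell, str) and cell.strip() in ("", ".", "./.", "NA")


def _parse_call(cell, mapping: dict[str, str]) -> int | None:
    if _is_na(cell):
        return None
    parts = str(cell).strip().split("/")
    if len(parts) != 2:
        return None
    alleles = []
    for p in parts:
        a = mapping.get(p.strip())
        if a is None:
            return None
        alleles.append(a)
    return sum(1 for a in alleles if a == "I")


def write_genotype_table(gm: GenotypeMatrix, sink, dialect: str = "ID",
                         sep: str | None = None,
                         missing: str = "./.") -> None:
    """Write a genotype table readable by :func:`read_genotype_table`."""
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    inv = {}
    for ext, internal in DIALECTS[dialect].items():
        inv.setdefault(internal, ext)
    sep = _resolve_sep(sink, sep)
    cell_for = {
        MISSING: missing,
        0: f"{inv['D']}/{inv['D']}",
        1: f"{inv['I']}/{inv['D']}",
        2: f"{inv['I']}/{inv['I']}",
    }
    rows = []
    for i, ind in enumerate(gm.individuals):
        rows.append([ind] + [cell_for[int(c)] for c in gm.calls[i]])
    df = pd.DataFrame(rows, columns=["sample"] + gm.locus_ids)
    df.to_csv(sink, sep=sep, index=False)


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def count_genotypes(gm: GenotypeMatrix, locus: LocusDef | str) -> GenotypeCounts:
    """Tally II/ID/DD calls at one locus, excluding missing calls."""
    j = gm.locus_index(locus)
    col = gm.calls[:, j]
    lid = gm.locus_ids[j]
    n_ii = int((col == 2).sum())
    n_id = int((col == 1).sum())
    n_dd = int((col == 0).sum())
    return GenotypeCounts(lid, n_ii, n_id, n_dd)  # raises if all missing


def estimate_allele_freqs(gc: GenotypeCounts) -> AlleleFrequency:
    """Allele frequencies by gene counting: p_ins = (2 n_II + n_ID) / 2n."""
    p_ins = (2 * gc.n_ii + gc.n_id) / (2 * gc.n)
    return AlleleFrequency(p_ins, 1.0 - p_ins)


def reconstruct_counts(p_ins: float, ho: float, n: int,
                       locus_id: str = "locus") -> GenotypeCounts:
    """Invert published summaries (DIP+ frequency, Ho, n) to genotype counts.

    Published tables print p and Ho at 4 decimals; at moderate n the integer
    count triple is uniquely determined.  Nearest-integer rounding is applied
    and the result re-checked: if re-deriving p and Ho does not reproduce the
    inputs at 4 decimals, there is no consistent solution and an error is
    raised rather than returning a silently wrong triple.
    """
    if not (0.0 <= p_ins <= 1.0 and 0.0 <= ho <= 1.0):
        raise ValueError("p_ins and ho must lie in [0, 1]")
    if n <= 0:
        raise ValueError("n must be positive")
    n_id = round(ho * n)
    n_ii = round((2 * n * p_ins - n_id) / 2)
    n_dd = n - n_id - n_ii
    if min(n_ii, n_id, n_dd) < 0:
        raise ValueError(
            f"{locus_id}: inconsistent summary (p={p_ins}, ho={ho}, n={n}): "
            "no non-negative integer solution"
        )
    gc = GenotypeCounts(locus_id, n_ii, n_id, n_dd)
    p_back = round4(estimate_allele_freqs(gc).p_ins)
    ho_back = round4(gc.n_id / gc.n)
    if p_back != round4(p_ins) or ho_back != round4(ho):
        raise ValueError(
            f"{locus_id}: inconsistent summary: reconstruction gives "
            f"p={p_back}, ho={ho_back}, expected p={round4(p_ins)}, "
            f"ho={round4(ho)}"
        )
    return gc


# ---------------------------------------------------------------------------
# frequency table I/O
# ---------------------------------------------------------------------------

def read_freq_table(source) -> FreqTable:
    """Read a frequency CSV: columns ``population``, ``n``, one per locus."""
    df = pd.read_csv(source)
    if df.shape[1] < 3 or df.columns[0] != "population" or "n" not in df.columns:
        raise ValueError(
            "frequency table needs columns: population, n, then one DIP+ "
            "frequency column per locus"
        )
    df = df.set_index("population")
    return FreqTable.from_frame(df)


def write_freq_table(ft: FreqTable, sink) -> None:
    ft.to_frame().to_csv(sink, float_format="%.17g")
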