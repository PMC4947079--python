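"""Generators emulating the study design of a forensic InDel panel survey.

The reference scale throughout is a sample of 136 diploid individuals typed
at 30 unlinked biallelic InDel loci, the shape of the packaged study
fixture.  Three generators cover the pipeline's input space:

* :func:`simulate_genotypes` — one population, per-locus insertion-allele
  frequencies, with an inbreeding coefficient ``f`` controlling departure
  from Hardy-Weinberg proportions (f = 0 gives HWE; f > 0 heterozygote
  deficit; f < 0 excess).
* :func:`simulate_populations_bn` — K populations diverged from shared
  ancestral frequencies under the Balding-Nichols model: subpopulation
  frequencies are Beta-distributed with mean p and variance F p (1 - p),
  so the divergence parameter F equals the expected Fst.
* :func:`simulate_ld_pair` — two loci with a chosen gametic disequilibrium
  D, sampled as haplotype pairs.

Reproducibility: every generator takes a seed; a root seed is split into
per-locus / per-population substreams via ``numpy.random.SeedSequence``
spawn keys, so extending the panel never perturbs earlier loci's draws.

The module also exposes the packaged study fixture: the 30-locus
frequency/heterozygosity summary table and the 22-population DA distance
matrix, checksum-verified on load.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from io import StringIO

import numpy as np
import pandas as pd

from .genotype_model import (
    AlleleFrequency,
    FreqTable,
    GenotypeCounts,
    GenotypeMatrix,
    LocusDef,
    reconstruct_counts,
)
from .population_comparison import DistanceMatrix, read_distance_matrix

__all__ = [
    "SimConfig",
    "simulate_genotypes",
    "simulate_populations_bn",
    "simulate_ld_pair",
    "fixture_study",
    "fixture_table1",
    "study_loci",
    "STUDY_N",
]

STUDY_N = 136  # diploid sample size of the packaged study fixture


@dataclass
class SimConfig:
    """Parameters for one simulated population sample."""

    n: int
    freqs: list[float]
    f: float = 0.0
    seed: int = field(default=None)  # type: ignore[assignment]
    locus_ids: list[str] | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory for stochastic generators")
        if self.n <= 0:
            raise ValueError("n must be positive")
        for p in self.freqs:
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"frequency {p} outside [0, 1]")
            _check_f(p, self.f)
        if self.locus_ids is not None and len(self.locus_ids) != len(self.freqs):
            raise ValueError("locus_ids length must match freqs")


def _check_f(p: float, f: float) -> None:
    """f must keep all three genotype probabilities non-negative."""
    q = 1.0 - p
    if f > 1.0:
        raise ValueError("inbreeding coefficient f cannot exceed 1")
    if p in (0.0, 1.0):
        return
    lower = -min(p / q, q / p)
    if f < lower - 1e-12:
        raise ValueError(
            f"f={f} infeasible for p={p}: must be >= {lower:.6g}"
        )


def _locus_rngs(seed: int, count: int, stream: int = 0):
    """Independent per-locus generators from one root seed.

    Substream k uses spawn key (stream, k), so adding loci (or a second
    population via a different ``stream``) leaves earlier draws unchanged.
    """
    return [np.random.default_rng(np.random.SeedSequence(
        seed, spawn_key=(stream, k))) for k in range(count)]


def simulate_genotypes(cfg: SimConfig) -> GenotypeMatrix:
    """Sample diploid genotypes with optional inbreeding-style HWE departure.

    Genotype probabilities per locus: (p^2 + f p q, 2 p q (1 - f),
    q^2 + f p q), independent across individuals and loci.
    """
    loci = [LocusDef(lid) for lid in (cfg.locus_ids or
                                      [f"L{k + 1:02d}" for k in
                                       range(len(cfg.freqs))])]
    calls = np.empty((cfg.n, len(loci)), dtype=np.int8)
    for k, (p, rng) in enumerate(zip(cfg.freqs,
                                     _locus_rngs(cfg.seed, len(loci)))):
        q = 1.0 - p
        probs = np.array([p * p + cfg.f * p * q,
                          2 * p * q * (1 - cfg.f),
                          q * q + cfg.f * p * q])
        probs = np.clip(probs, 0.0, None)
        probs /= probs.sum()
        # category 0 = II (dose 2), 1 = ID, 2 = DD
        draw = rng.choice(3, size=cfg.n, p=probs)
        calls[:, k] = 2 - draw
    individuals = [f"S{i + 1:04d}" for i in range(cfg.n)]
    return GenotypeMatrix(individuals, loci, calls)


def simulate_populations_bn(ancestral_freqs, F: float, K: int, n: int,
                            seed: int) -> list[GenotypeMatrix]:
    """K populations diverged under the Balding-Nichols model.

    Each population draws its per-locus frequency from
    Beta(p (1-F)/F, (1-p)(1-F)/F) — mean p, variance F p (1-p) — and then
    samples HWE genotypes at that frequency.  F is the expected Fst between
    any pair of populations.
    """
    if not (0.0 < F < 1.0):
        raise ValueError("Balding-Nichols F must lie in (0, 1)")
    if K < 1 or n < 1:
        raise ValueError("K and n must be positive")
    ancestral_freqs = list(ancestral_freqs)
    shape = (1.0 - F) / F
    pops = []
    for g in range(K):
        rngs = _locus_rngs(seed, len(ancestral_freqs), stream=g + 1)
        local = []
        for p, rng in zip(ancestral_freqs, rngs):
            if p in (0.0, 1.0):
                local.append(p)
            else:
                local.append(float(rng.beta(p * shape, (1.0 - p) * shape)))
        # offset sub-seed for the genotype draw of this population
        cfg = SimConfig(n=n, freqs=local, f=0.0,
                        seed=_sub_seed(seed, g))
        gm = simulate_genotypes(cfg)
        gm.individuals = [f"P{g + 1}_{s}" for s in gm.individuals]
        pops.append(gm)
    return pops


def _sub_seed(seed: int, index: int) -> int:
    return int(np.random.SeedSequence(seed, spawn_key=(99, index))
               .generate_state(1)[0] % (2 ** 31))


def simulate_ld_pair(p_a: float, p_b: float, d: float, n: int,
                     seed: int) -> GenotypeMatrix:
    """Two loci with gametic disequilibrium D, as paired haplotypes.

    Haplotype frequencies (pA pB + D, pA qB - D, qA pB - D, qA qB + D) must
    all be non-negative: D is bounded by
    max(-pA pB, -qA qB) <= D <= min(pA qB, qA pB).
    """
    qa, qb = 1.0 - p_a, 1.0 - p_b
    lo = max(-p_a * p_b, -qa * qb)
    hi = min(p_a * qb, qa * p_b)
    if not (lo - 1e-12 <= d <= hi + 1e-12):
        raise ValueError(
            f"D={d} infeasible for pA={p_a}, pB={p_b}: admissible interval "
            f"[{lo:.6g}, {hi:.6g}]"
        )
    hap = np.array([p_a * p_b + d, p_a * qb - d, qa * p_b - d, qa * qb + d])
    hap = np.clip(hap, 0.0, None)
    hap /= hap.sum()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    draws = rng.choice(4, size=(n, 2), p=hap)
    # haplotype code -> (allele at A, allele at B); 1 = insertion
    a_allele = np.isin(draws, (0, 1)).astype(np.int8)
    b_allele = np.isin(draws, (0, 2)).astype(np.int8)
    calls = np.stack([a_allele.sum(axis=1), b_allele.sum(axis=1)], axis=1)
    individuals = [f"S{i + 1:04d}" for i in range(n)]
    return GenotypeMatrix(individuals,
                          [LocusDef("LA"), LocusDef("LB")],
                          calls.astype(np.int8))


# ---------------------------------------------------------------------------
# packaged study fixture
# ---------------------------------------------------------------------------

def _load_resource(name: str) -> str:
    pkg = resources.files("indelpop.data")
    text = (pkg / name).read_text()
    checksums = json.loads((pkg / "checksums.json").read_text())
    digest = hashlib.sha256(text.encode()).hexdigest()
    if digest != checksums[name]:
        raise ValueError(
            f"fixture {name} checksum mismatch: file corrupted or modified"
        )
    return text


def fixture_table1() -> pd.DataFrame:
    """The packaged 30-locus summary table (one row per locus).

    Columns: locus, rs_id, cytoband, dip_plus, dip_minus, mp, pd, pic, pe,
    tpi, ho, he, hwe_p, n.  The hwe_p column is the source publication's
    printed value, retained as data (see the methods note on exact-test
    variants); all other statistic columns are reproducible from
    (dip_plus, ho, n) via count reconstruction.
    """
    return pd.read_csv(StringIO(_load_resource("table1_xinjiang_uigur.csv")))


def fixture_study() -> tuple[FreqTable, list[GenotypeCounts], DistanceMatrix]:
    """Frequency table, reconstructed genotype counts, and the DA matrix.

    The FreqTable holds the single studied population's DIP+ frequencies;
    the counts are the unique integer triples reproducing each locus's
    printed (frequency, Ho) pair at n = 136; the DistanceMatrix is the
    published 22-population DA matrix.
    """
    t1 = fixture_table1()
    n = int(t1["n"].iloc[0])
    freqs = [AlleleFrequency.of_ins(float(p)) for p in t1["dip_plus"]]
    ft = FreqTable(populations=["Xinjiang Uigur"], sample_sizes=[n],
                   loci=list(t1["locus"]), freqs=[freqs])
    counts = [
        reconstruct_counts(float(r.dip_plus), float(r.ho), int(r.n),
                           locus_id=str(r.locus))
        for r in t1.itertuples()
    ]
    dm = read_distance_matrix(StringIO(_load_resource("table2_da_matrix.csv")))
    return ft, counts, dm


def study_loci() -> list[LocusDef]:
    """LocusDef annotations (rs number, cytoband) for the 30-locus panel."""
    t1 = fixture_table1()
    return [LocusDef(locus_id=str(r.locus), rs_id=int(r.rs_id),
                     cytoband=str(r.cytoband)) for r in t1.itertuples()]
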