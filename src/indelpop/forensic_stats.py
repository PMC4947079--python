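"""Forensic efficiency statistics and Hardy-Weinberg screening for a panel.

Per-locus statistics follow the conventions of forensic population reports
for biallelic markers:

* Ho — observed heterozygosity, ``n_ID / n``.
* He — unbiased expected heterozygosity, ``n/(n-1) * (1 - sum p_i^2)``.
* MP — match probability, the chance two random individuals share a
  genotype, computed from *observed* genotype proportions; PD = 1 - MP.
* PIC — polymorphic information content (Botstein), biallelic form
  ``1 - (p^2 + q^2) - 2 p^2 q^2``.
* PE — power of exclusion from observed heterozygosity h (H = 1 - h):
  ``h^2 (1 - 2 h H^2)``.
* TPI — typical paternity index ``1 / (2 (1 - Ho))``.

Panel-level: CPD = 1 - prod(MP_i), CPE = 1 - prod(1 - PE_i).

The Hardy-Weinberg test is the exact conditional (Levene) test: conditioning
on the observed allele counts, every heterozygote count of matching parity
is enumerated and the two-sided p-value is the summed probability of all
configurations no more probable than the observed one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_model import AlleleFrequency, GenotypeCounts, LocusDef, \
    estimate_allele_freqs, round4

__all__ = [
    "LocusForensics",
    "PanelForensics",
    "obs_het",
    "exp_het_unbiased",
    "match_probability",
    "pic",
    "power_of_exclusion",
    "typical_paternity_index",
    "hwe_exact_test",
    "bonferroni_screen",
    "locus_forensics",
    "combined_panel",
    "panel_from_counts",
    "locus_report",
]


def obs_het(gc: GenotypeCounts) -> float:
    """Observed heterozygosity: fraction of heterozygous individuals."""
    return gc.n_id / gc.n


def exp_het_unbiased(af: AlleleFrequency, n: int) -> float:
    """Unbiased expected heterozygosity with the n/(n-1) small-sample factor."""
    if n < 2:
        raise ValueError("unbiased He needs n >= 2")
    return n / (n - 1) * (1.0 - af.p_ins ** 2 - af.p_del ** 2)


def match_probability(gc: GenotypeCounts) -> tuple[float, float]:
    """Match probability from observed genotype proportions, and PD = 1 - MP."""
    n = gc.n
    mp = sum((c / n) ** 2 for c in gc.as_tuple())
    return mp, 1.0 - mp


def pic(af: AlleleFrequency) -> float:
    """Polymorphic information content, biallelic Botstein form."""
    p, q = af.p_ins, af.p_del
    return 1.0 - (p * p + q * q) - 2.0 * p * p * q * q


def power_of_exclusion(ho: float) -> float:
    """Power of exclusion from observed heterozygosity."""
    if not (0.0 <= ho <= 1.0):
        raise ValueError("ho must lie in [0, 1]")
    h, hh = ho, 1.0 - ho
    return h * h * (1.0 - 2.0 * h * hh * hh)


def typical_paternity_index(ho: float) -> float:
    """Typical paternity index 1 / (2 (1 - Ho))."""
    if not (0.0 <= ho <= 1.0):
        raise ValueError("ho must lie in [0, 1]")
    if ho == 1.0:
        raise ValueError("TPI undefined at ho = 1 (no homozygotes observed)")
    return 1.0 / (2.0 * (1.0 - ho))


# ---------------------------------------------------------------------------
# exact Hardy-Weinberg test
# ---------------------------------------------------------------------------

def _levene_log_probs(n_a: int, n_b: int):
    """Log conditional probabilities of each heterozygote count.

    Given allele counts (n_a, n_b) in a sample of n = (n_a + n_b)/2 diploids,
    the Levene distribution over the heterozygote count h is

        P(h | n_a, n_b) = n! / (n_AA! h! n_BB!) * 2^h * n_a! n_b! / (2n)!

    with n_AA = (n_a - h)/2, n_BB = (n_b - h)/2; h runs over the counts with
    the parity of min(n_a, n_b).  Returns (hets, logprobs) arrays.
    """
    n = (n_a + n_b) // 2
    rare = min(n_a, n_b)
    hets = np.arange(rare % 2, rare + 1, 2)
    n_aa = (n_a - hets) // 2
    n_bb = (n_b - hets) // 2
    lg = math.lgamma
    const = lg(n + 1) + lg(n_a + 1) + lg(n_b + 1) - lg(2 * n + 1)
    logp = (const + hets * math.log(2.0)
            - np.array([lg(x + 1) for x in n_aa])
            - np.array([lg(x + 1) for x in hets])
            - np.array([lg(x + 1) for x in n_bb]))
    return hets, logp


def hwe_exact_test(gc: GenotypeCounts, midp: bool = False) -> float:
    """Two-sided exact test of Hardy-Weinberg proportions.

    Sums the Levene conditional probabilities of every heterozygote
    configuration no more probable than the observed one.  With
    ``midp=True`` only half the observed configuration's probability is
    counted (mid-p variant); the default matches the standard convention.
    Returns 1.0 when one allele is unobserved (the test is vacuous).
    """
    n_a = 2 * gc.n_ii + gc.n_id
    n_b = 2 * gc.n_dd + gc.n_id
    if min(n_a, n_b) == 0:
        return 1.0
    hets, logp = _levene_log_probs(n_a, n_b)
    probs = np.exp(logp)
    p_obs = probs[np.searchsorted(hets, gc.n_id)]
    # tolerance absorbs floating-point ties in the enumeration
    include = probs <= p_obs * (1.0 + 1e-12)
    # all configurations included => the conditional law sums to exactly 1
    p = 1.0 if include.all() else float(probs[include].sum())
    if midp:
        p -= 0.5 * p_obs
    return float(min(1.0, p))


def bonferroni_screen(pvalues, alpha: float = 0.05):
    """Bonferroni-adjusted threshold alpha/m and the indices falling below it."""
    pvalues = list(pvalues)
    if not pvalues:
        raise ValueError("need at least one p-value")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    threshold = alpha / len(pvalues)
    flagged = [i for i, p in enumerate(pvalues) if p < threshold]
    return threshold, flagged


# ---------------------------------------------------------------------------
# per-locus and panel aggregation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LocusForensics:
    locus_id: str
    p_ins: float
    ho: float
    he: float
    mp: float
    pd: float
    pic: float
    pe: float
    tpi: float
    hwe_p: float


@dataclass(frozen=True)
class PanelForensics:
    per_locus: list[LocusForensics]
    cpd: float
    cpe: float
    bonferroni_level: float
    hwe_flags: list[str]

    def cpd_str(self, decimals: int = 14) -> str:
        return f"{self.cpd:.{decimals}f}"


def locus_forensics(gc: GenotypeCounts, midp: bool = False) -> LocusForensics:
    """All per-locus statistics from one genotype count triple."""
    af = estimate_allele_freqs(gc)
    ho = obs_het(gc)
    mp, pd_ = match_probability(gc)
    return LocusForensics(
        locus_id=gc.locus_id,
        p_ins=af.p_ins,
        ho=ho,
        he=exp_het_unbiased(af, gc.n),
        mp=mp,
        pd=pd_,
        pic=pic(af),
        pe=power_of_exclusion(ho),
        tpi=typical_paternity_index(ho) if ho < 1.0 else float("nan"),
        hwe_p=hwe_exact_test(gc, midp=midp),
    )


def combined_panel(per_locus: list[LocusForensics],
                   alpha: float = 0.05) -> PanelForensics:
    """Combine per-locus statistics into CPD/CPE and the HWE screen."""
    if not per_locus:
        raise ValueError("need at least one locus")
    cpd = 1.0 - math.prod(lf.mp for lf in per_locus)
    cpe = 1.0 - math.prod(1.0 - lf.pe for lf in per_locus)
    threshold, flagged = bonferroni_screen([lf.hwe_p for lf in per_locus],
                                           alpha)
    return PanelForensics(
        per_locus=per_locus,
        cpd=cpd,
        cpe=cpe,
        bonferroni_level=threshold,
        hwe_flags=[per_locus[i].locus_id for i in flagged],
    )


def panel_from_counts(counts: list[GenotypeCounts], alpha: float = 0.05,
                      midp: bool = False) -> PanelForensics:
    return combined_panel([locus_forensics(gc, midp=midp) for gc in counts],
                          alpha=alpha)


def locus_report(panel: PanelForensics,
                 loci: list[LocusDef] | None = None) -> pd.DataFrame:
    """Report table in the column order of published forensic panels.

    Statistics are rounded half-up to 4 decimals for display; the
    ``PanelForensics`` object retains full precision.
    """
    ann = {l.locus_id: l for l in (loci or [])}
    rows = []
    for lf in panel.per_locus:
        l = ann.get(lf.locus_id)
        rows.append({
            "locus": lf.locus_id,
            "rs_id": l.rs_id if l else None,
            "cytoband": l.cytoband if l else None,
            "dip_plus": round4(lf.p_ins),
            "dip_minus": round4(1.0 - lf.p_ins),
            "mp": round4(lf.mp),
            "pd": round4(lf.pd),
            "pic": round4(lf.pic),
            "pe": round4(lf.pe),
            "tpi": round4(lf.tpi),
            "ho": round4(lf.ho),
            "he": round4(lf.he),
            "hwe_p": round4(lf.hwe_p),
        })
    return pd.DataFrame(rows)
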