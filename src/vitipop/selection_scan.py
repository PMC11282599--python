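"""Positive-selection evidence battery with a ≥ k-of-n vote.

Four site/window statistics are computed per (variant, population):

* Hardy-Weinberg χ² — departure of genotype counts from HWE expectations;
* ΔDAF — difference in derived-allele frequency between the target
  population and a reference (requires an ancestral-allele annotation);
* Weir-Cockerham Fst between the target population and the reference;
* Tajima's D in a window around the variant — negative values indicate an
  excess of rare variants, consistent with a recent sweep.

Each test is thresholded into a boolean flag and a variant is called
"under positive selection" in a population when at least ``k`` flags are
raised (default k = 3). Undefined tests (monomorphic site, S = 0 window,
missing ancestral allele) count toward neither side; they shrink the
effective panel, which is reported. Haplotype-based statistics (iHS and
kin) need phased data and are out of scope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist

from .popio import MISSING, GenotypeMatrix, GroupLevel, SamplePanel
from .prioritization import wc_fst

logger = logging.getLogger(__name__)


def hwe_chi_square(n_AA: int, n_Aa: int, n_aa: int) -> tuple[float, float]:
    """1-df goodness-of-fit χ² of genotype counts against HWE proportions
    computed from the sample allele frequency. Returns (statistic, p).

    A monomorphic sample is in trivial HWE: (0, 1) by convention.
    """
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("need at least one genotype")
    p = (2 * n_AA + n_Aa) / (2 * n)
    if p in (0.0, 1.0):
        logger.debug("monomorphic sample; HWE trivially satisfied")
        return 0.0, 1.0
    q = 1 - p
    exp = np.array([n * p * p, 2 * n * p * q, n * q * q])
    obs = np.array([n_AA, n_Aa, n_aa], dtype=float)
    stat = float(((obs - exp) ** 2 / exp).sum())
    return stat, float(chi2_dist.sf(stat, df=1))


def delta_daf(target_daf: float, reference_daf: float) -> float:
    """Difference of derived allele frequency, target − reference ∈ [−1, 1]."""
    for v in (target_daf, reference_daf):
        if not (0 <= v <= 1):
            raise ValueError(f"DAF must lie in [0, 1], got {v}")
    return target_daf - reference_daf


def derived_freq(alt_freq: float, ref: str, alt: str, ancestral: str | None) -> float | None:
    """Polarise an ALT frequency into a derived-allele frequency.

    Returns None (site skipped) when the ancestral allele is unknown or
    matches neither REF nor ALT.
    """
    if ancestral is None:
        return None
    anc = ancestral.upper()
    if anc == ref.upper():
        return alt_freq  # ALT is derived
    if anc == alt.upper():
        return 1 - alt_freq  # REF is derived
    return None


def tajima_constants(n: int) -> dict[str, float]:
    """The standard constants of Tajima's D for n sequences (chromosomes)."""
    if n < 4:
        raise ValueError("need at least 4 chromosomes")
    i = np.arange(1, n)
    a1 = float((1.0 / i).sum())
    a2 = float((1.0 / i**2).sum())
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2,
            "c1": c1, "c2": c2, "e1": e1, "e2": e2}


@dataclass
class TajimaDResult:
    chrom: str
    start: int  # half-open [start, end)
    end: int
    n: int  # chromosomes
    S: int  # segregating sites
    pi: float  # mean pairwise differences
    D: float  # NaN when undefined (S = 0)
    constants: dict[str, float] = field(default_factory=dict)

    @property
    def defined(self) -> bool:
        return not np.isnan(self.D)


def tajimas_d(
    gm: GenotypeMatrix,
    samples: Sequence[str],
    chrom: str,
    start: int,
    end: int,
) -> TajimaDResult:
    """Tajima's D over the window [start, end) for one population.

    π is computed from allele counts per site (mean pairwise difference
    2k(n−k)/(n(n−1)) for k derived/alternate copies among n chromosomes);
    the constants use the window-wide chromosome count, so sites with
    missing genotypes should be rare (they are counted with their own n in
    π). S = 0 leaves D undefined (NaN, flagged via ``defined``).
    """
    idx = gm.sample_indices(samples)
    in_win = [
        i for i, l in enumerate(gm.loci)
        if l.chrom == chrom and start <= l.pos < end
    ]
    n_chrom_full = 2 * len(idx)
    if n_chrom_full < 4:
        raise ValueError("need at least 4 chromosomes")
    const = tajima_constants(n_chrom_full)
    S = 0
    pi = 0.0
    for i in in_win:
        row = gm.dosages[i, idx]
        obs = row != MISSING
        n = 2 * int(obs.sum())
        if n < 2:
            continue
        k = int(row[obs].sum())
        if 0 < k < n:
            S += 1
            pi += 2 * k * (n - k) / (n * (n - 1))
    if S == 0:
        return TajimaDResult(chrom, start, end, n_chrom_full, 0, 0.0,
                             float("nan"), const)
    var = const["e1"] * S + const["e2"] * S * (S - 1)
    D = (pi - S / const["a1"]) / np.sqrt(var)
    return TajimaDResult(chrom, start, end, n_chrom_full, S, pi, float(D), const)


@dataclass
class SelectionThresholds:
    """Per-test flag thresholds (explicit configuration, recorded in output)."""

    alpha_hwe: float = 0.05    # HWE p <= alpha_hwe
    tau_daf: float = 0.3       # ΔDAF >= tau_daf
    tau_fst: float = 0.25      # Fst >= tau_fst
    tau_d: float = -1.5        # Tajima's D <= tau_d
    window: int = 10_000       # bp, centred on the focal variant
    k: int = 3                 # vote threshold


def selection_vote(flags: Mapping[str, bool | None], k: int = 3) -> tuple[int, int, bool]:
    """Combine per-test flags into a verdict.

    Returns (votes, n_available, verdict). Tests with value None are
    unavailable and count toward neither side. ``k`` larger than the number
    of configured tests is an error.
    """
    if k > len(flags):
        raise ValueError(f"k={k} exceeds the {len(flags)} configured tests")
    available = {t: v for t, v in flags.items() if v is not None}
    votes = sum(available.values())
    return votes, len(available), votes >= k


def selection_scan(
    gm: GenotypeMatrix,
    panel: SamplePanel,
    targets: Sequence[int],
    populations: Sequence[str] | None = None,
    level: GroupLevel = "super",
    thresholds: SelectionThresholds | None = None,
) -> pd.DataFrame:
    """Run the test battery for each (target variant, population).

    The reference for ΔDAF and Fst is the rest of the cohort (every sample
    outside the tested population). One row per (variant, population) with
    per-test statistics, flags, vote count and verdict; thresholds are
    attached as table metadata.
    """
    th = thresholds or SelectionThresholds()
    groups = panel.groups(level)
    pops = list(populations) if populations is not None else sorted(groups)
    all_samples = set(gm.sample_ids)
    rows = []
    for v in targets:
        locus = gm.loci[v]
        for pop in pops:
            samples = groups[pop]
            idx = gm.sample_indices(samples)
            d = gm.dosages[v, idx]
            obs = d != MISSING
            dd = d[obs]
            n_AA, n_Aa, n_aa = int((dd == 2).sum()), int((dd == 1).sum()), int((dd == 0).sum())
            hwe_stat, hwe_p = hwe_chi_square(n_AA, n_Aa, n_aa)
            hwe_flag: bool | None = hwe_p <= th.alpha_hwe

            rest = sorted(all_samples - set(samples))
            ridx = gm.sample_indices(rest)
            rd = gm.dosages[v, ridx]
            robs = rd != MISSING
            p_pop = dd.sum() / (2 * len(dd)) if len(dd) else np.nan
            p_ref = rd[robs].sum() / (2 * int(robs.sum())) if robs.any() else np.nan

            daf_pop = derived_freq(p_pop, locus.ref, locus.alt, locus.ancestral)
            daf_ref = derived_freq(p_ref, locus.ref, locus.alt, locus.ancestral)
            if daf_pop is None or daf_ref is None:
                ddaf, daf_flag = np.nan, None
                if locus.ancestral is not None:
                    logger.info("site %s skipped for ΔDAF: ancestral %s matches "
                                "neither allele", locus.id, locus.ancestral)
            else:
                ddaf = delta_daf(daf_pop, daf_ref)
                daf_flag = ddaf >= th.tau_daf

            h_pop = (dd == 1).sum() / len(dd) if len(dd) else np.nan
            h_ref = (rd[robs] == 1).sum() / int(robs.sum()) if robs.any() else np.nan
            fst = wc_fst(
                [len(dd), int(robs.sum())], [p_pop, p_ref], [h_pop, h_ref]
            ).theta
            fst_flag = None if np.isnan(fst) else fst >= th.tau_fst

            half = th.window // 2
            td = tajimas_d(
                gm, samples, locus.chrom, max(1, locus.pos - half), locus.pos + half
            )
            d_flag = None if not td.defined else td.D <= th.tau_d

            flags = {"hwe": hwe_flag, "delta_daf": daf_flag,
                     "fst": fst_flag, "tajima_d": d_flag}
            votes, n_avail, verdict = selection_vote(flags, k=th.k)
            rows.append(
                {
                    "variant": v, "id": locus.id, "population": pop,
                    "hwe_p": hwe_p, "hwe_flag": hwe_flag,
                    "delta_daf": ddaf, "daf_flag": daf_flag,
                    "fst": fst, "fst_flag": fst_flag,
                    "tajima_d": td.D, "tajima_s": td.S, "d_flag": d_flag,
                    "votes": votes, "tests_available": n_avail,
                    "verdict": verdict,
                }
            )
    out = pd.DataFrame(rows)
    out.attrs["thresholds"] = {
        "alpha_hwe": th.alpha_hwe, "tau_daf": th.tau_daf, "tau_fst": th.tau_fst,
        "tau_d": th.tau_d, "window_bp": th.window, "k": th.k,
        "reference": "cohort excluding the tested population",
    }
    return out
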