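"""Ancillary-SNP prioritisation: MAF gate, Weir-Cockerham Fst, χ² + Bonferroni.

For each population pair, every biallelic SNP is pushed through three gates,
all of which must pass simultaneously for the SNP to be prioritised:

1. common-variant gate: minor allele frequency >= 0.05 (configurable mode:
   in all groups, any group, or one target group);
2. differentiation gate: per-SNP Weir & Cockerham (1984) θ̂ >= 0.5;
3. significance gate: 1-df χ² test of independence on the 2×2 allele-count
   table, Bonferroni-corrected over the variants in the pair scan, at
   α = 0.05.

θ̂ is the variance-components estimator a/(a+b+c) with a = among-population,
b = among-individuals-within-population and c = within-individual
components, computed from sample sizes, allele frequencies and *observed*
heterozygote proportions (no HWE assumption; an HWE fallback exists for
frequency-only input). It can be slightly negative by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist

from .popio import MISSING, GenotypeMatrix, GroupLevel, SamplePanel

MafMode = Literal["all_groups", "any_group", "target_group"]


@dataclass
class FstResult:
    """Weir-Cockerham variance components and θ̂ for one locus."""

    a: float  # among populations
    b: float  # among individuals within populations
    c: float  # within individuals
    theta: float  # a / (a + b + c); NaN when monomorphic in all populations
    n: tuple[float, ...]
    p: tuple[float, ...]

    @property
    def defined(self) -> bool:
        return not np.isnan(self.theta)


@dataclass
class ChiSquareResult:
    observed: np.ndarray  # 2x2
    expected: np.ndarray  # 2x2
    statistic: float
    df: int
    p: float
    p_bonferroni: float | None = None


def maf_filter(
    freq: pd.DataFrame,
    threshold: float = 0.05,
    mode: MafMode = "all_groups",
    target_group: str | None = None,
) -> set[int]:
    """Variant indices whose MAF meets ``threshold`` (inclusive) under the
    chosen mode. ``target_group`` mode gates on a single group's MAF."""
    if mode not in ("all_groups", "any_group", "target_group"):
        raise ValueError(f"unknown MAF filter mode {mode!r}")
    ok = freq["maf"] >= threshold
    if mode == "target_group":
        if target_group is None:
            raise ValueError("target_group mode requires target_group")
        sel = freq[freq["group"] == target_group]
        if sel.empty:
            raise ValueError(f"group {target_group!r} absent from frequency table")
        return set(sel.loc[ok, "variant"].tolist())
    grouped = ok.groupby(freq["variant"])
    keep = grouped.all() if mode == "all_groups" else grouped.any()
    return set(keep.index[keep].tolist())


def wc_fst_components(
    n: np.ndarray, p: np.ndarray, h: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weir & Cockerham (1984) variance components, vectorised over loci.

    Parameters are per-population arrays of shape (r,) or (r, m): ``n``
    sample sizes (individuals), ``p`` allele frequencies, ``h`` observed
    heterozygote proportions. Returns (a, b, c) arrays of shape (m,).
    """
    n = np.atleast_2d(np.asarray(n, dtype=float))
    p = np.atleast_2d(np.asarray(p, dtype=float))
    h = np.atleast_2d(np.asarray(h, dtype=float))
    r = n.shape[0]
    if r < 2:
        raise ValueError("need at least two populations")
    if (n < 2).any():
        raise ValueError("each population needs n >= 2 individuals")
    nbar = n.mean(axis=0)
    nc = (r * nbar - (n**2).sum(axis=0) / (r * nbar)) / (r - 1)
    pbar = (n * p).sum(axis=0) / (r * nbar)
    s2 = (n * (p - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
    hbar = (n * h).sum(axis=0) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    return a, b, c


def wc_fst(
    n: Sequence[float], p: Sequence[float], h: Sequence[float] | None = None
) -> FstResult:
    """θ̂ for one locus across two or more populations.

    ``h`` is the observed heterozygote proportion per population; when None,
    HWE proportions 2p(1-p) are assumed (frequency-only input path — flagged
    by the caller). A locus monomorphic in every population has no allelic
    variance and θ̂ is NaN.
    """
    n = np.asarray(n, dtype=float)
    p = np.asarray(p, dtype=float)
    if h is None:
        h = 2 * p * (1 - p)
    h = np.asarray(h, dtype=float)
    a, b, c = wc_fst_components(n[:, None], p[:, None], h[:, None])
    a, b, c = float(a[0]), float(b[0]), float(c[0])
    denom = a + b + c
    theta = a / denom if denom != 0 else float("nan")
    return FstResult(a=a, b=b, c=c, theta=theta, n=tuple(n), p=tuple(p))


def multilocus_fst(
    n: np.ndarray, p: np.ndarray, h: np.ndarray
) -> float:
    """Multi-locus Weir-Cockerham θ̂: ratio of summed variance components,
    Σa / Σ(a+b+c) over loci.

    This is the estimator of choice for recovering a genome-wide
    differentiation parameter: averaging per-locus ratios instead is biased
    downward because each locus's denominator is itself noisy.
    """
    a, b, c = wc_fst_components(n, p, h)
    denom = (a + b + c).sum()
    if denom == 0:
        return float("nan")
    return float(a.sum() / denom)


def pair_stats(
    gm: GenotypeMatrix, panel: SamplePanel, group: str, level: GroupLevel
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(n, p, h) per variant for one group: non-missing sample count,
    ALT frequency, observed heterozygote proportion."""
    samples = panel.groups(level)[group]
    idx = gm.sample_indices(samples)
    sub = gm.dosages[:, idx]
    obs = sub != MISSING
    n = obs.sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(obs, sub, 0).sum(axis=1) / np.maximum(2 * n, 1)
        h = (sub == 1).sum(axis=1) / np.maximum(n, 1)
    return n, p, h


def chi_square_test(
    table, m: int | None = None, yates: bool = False
) -> ChiSquareResult:
    """χ² test of independence on a 2×2 allele-count table.

    Expected counts come from the margins; the statistic is
    Σ (Obs − Exp)²/Exp over the four cells with 1 degree of freedom and an
    upper-tail p (the statistic is two-sided in the frequency difference).
    No continuity correction by default. A zero margin leaves the test
    undefined and raises.
    """
    if hasattr(table, "a"):
        obs = np.array([[table.a, table.b], [table.c, table.d]], dtype=float)
    else:
        obs = np.asarray(table, dtype=float).reshape(2, 2)
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    total = obs.sum()
    if total == 0 or (row == 0).any() or (col == 0).any():
        raise ValueError("zero margin: chi-square test undefined")
    exp = row @ col / total
    diff = np.abs(obs - exp)
    if yates:
        diff = np.maximum(diff - 0.5, 0)
    stat = float((diff**2 / exp).sum())
    p = float(chi2_dist.sf(stat, df=1))
    return ChiSquareResult(
        observed=obs,
        expected=exp,
        statistic=stat,
        df=1,
        p=p,
        p_bonferroni=None if m is None else bonferroni_adjust(p, m),
    )


def bonferroni_adjust(p: float, m: int) -> float:
    """Family-wise error control: min(1, m·p)."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return min(1.0, m * p)


@dataclass
class Thresholds:
    maf_min: float = 0.05
    fst_min: float = 0.5
    alpha: float = 0.05
    maf_mode: MafMode = "all_groups"
    maf_target: str | None = None
    yates: bool = False


def prioritize(
    gm: GenotypeMatrix,
    panel: SamplePanel,
    pairs: Sequence[tuple[str, str]],
    thresholds: Thresholds | None = None,
    level: GroupLevel = "super",
    audit: bool = False,
) -> pd.DataFrame:
    """Scan population pairs for strongly differentiated common SNPs.

    For each (group1, group2) pair every variant is scored on the three
    gates (MAF, Fst, Bonferroni-χ²); the Bonferroni family is the set of
    variants with a defined χ² in that pair's scan. The returned table
    carries one row per prioritised variant — or per tested variant when
    ``audit=True``, with per-criterion pass flags.
    """
    th = thresholds or Thresholds()
    frames = []
    for g1, g2 in pairs:
        n1, p1, h1 = pair_stats(gm, panel, g1, level)
        n2, p2, h2 = pair_stats(gm, panel, g2, level)
        maf1 = np.minimum(p1, 1 - p1)
        maf2 = np.minimum(p2, 1 - p2)
        if th.maf_mode == "all_groups":
            maf_ok = (maf1 >= th.maf_min) & (maf2 >= th.maf_min)
        elif th.maf_mode == "any_group":
            maf_ok = (maf1 >= th.maf_min) | (maf2 >= th.maf_min)
        else:
            tgt = th.maf_target
            if tgt == g1:
                maf_ok = maf1 >= th.maf_min
            elif tgt == g2:
                maf_ok = maf2 >= th.maf_min
            else:
                raise ValueError(f"maf_target {tgt!r} not in pair ({g1}, {g2})")

        a, b, c = wc_fst_components(
            np.stack([n1, n2]), np.stack([p1, p2]), np.stack([h1, h2])
        )
        with np.errstate(invalid="ignore", divide="ignore"):
            theta = np.where(a + b + c != 0, a / (a + b + c), np.nan)
        fst_ok = theta >= th.fst_min

        # vectorised 2x2 chi-square over variants
        alt1, alt2 = 2 * n1 * p1, 2 * n2 * p2
        tot1, tot2 = 2 * n1, 2 * n2
        obs = np.stack([alt1, tot1 - alt1, alt2, tot2 - alt2], axis=1)
        rows = np.stack([tot1, tot2], axis=1)
        cols = np.stack([alt1 + alt2, tot1 + tot2 - alt1 - alt2], axis=1)
        total = tot1 + tot2
        defined = (rows > 0).all(axis=1) & (cols > 0).all(axis=1)
        exp = np.einsum("vi,vj->vij", rows, cols) / np.maximum(total, 1)[:, None, None]
        exp = exp.reshape(-1, 4)
        diff = np.abs(obs - exp)
        if th.yates:
            diff = np.maximum(diff - 0.5, 0)
        with np.errstate(invalid="ignore", divide="ignore"):
            stat = np.where(defined, (diff**2 / np.maximum(exp, 1e-300)).sum(axis=1), np.nan)
        praw = chi2_dist.sf(stat, df=1)
        m = int(defined.sum())
        p_bonf = np.minimum(1.0, m * praw)
        chi_ok = defined & (p_bonf <= th.alpha)

        passed = maf_ok & fst_ok & chi_ok
        df = pd.DataFrame(
            {
                "variant": np.arange(gm.n_variants),
                "id": [l.id for l in gm.loci],
                "chrom": [l.chrom for l in gm.loci],
                "pos": [l.pos for l in gm.loci],
                "pair": f"{g1}:{g2}",
                "maf1": maf1,
                "maf2": maf2,
                "fst": theta,
                "chi2": stat,
                "p": praw,
                "p_bonferroni": p_bonf,
                "m_tests": m,
                "pass_maf": maf_ok,
                "pass_fst": fst_ok,
                "pass_chi2": chi_ok,
                "prioritised": passed,
            }
        )
        frames.append(df if audit else df[passed].copy())
    out = pd.concat(frames, ignore_index=True)
    out.attrs["thresholds"] = {
        "maf_min": th.maf_min,
        "fst_min": th.fst_min,
        "alpha": th.alpha,
        "maf_mode": th.maf_mode,
        "bonferroni_family": "variants tested within one population-pair scan",
    }
    return out
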