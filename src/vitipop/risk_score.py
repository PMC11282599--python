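"""Unweighted genetic risk scores and the ancestry-bias subset analysis.

The per-individual genetic risk score over I risk SNPs is

    GRS = sum_i X_i / (2 I),    X_i in {0, 1, 2}

the fraction of risk alleles carried, bounded in [0, 1]. Scores are
summarised per population group (min/Q1/median/Q3/max) against the pooled
"global normal" median. The bias analysis recomputes group medians on
nested random subsets of risk alleles drawn within discovery-ancestry
strata (the classic design: Set1 = 2 EAS + 8 EUR, Set2 = Set1 + 5 EUR,
Set3 = 10 EUR) to check that scores are driven by allele frequencies, not
by which ancestry the alleles were discovered in.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .popio import MISSING, AlignedRiskMatrix, GroupLevel, RiskAllele, SamplePanel

QUARTILE_METHOD = "linear"  # interpolation convention, recorded in outputs


def genetic_risk_score(arm: AlignedRiskMatrix, strict: bool = False) -> pd.DataFrame:
    """Per-sample GRS table: columns ``sample``, ``score``, ``n_snps_used``.

    For samples with missing risk dosages the denominator uses that sample's
    non-missing SNP count (score stays a per-allele fraction); ``strict=True``
    instead sets such samples' scores to NaN. A sample with zero non-missing
    dosages gets NaN either way.
    """
    if arm.n_alleles == 0:
        raise ValueError("no aligned risk alleles")
    d = arm.dosages
    obs = d != MISSING
    n_used = obs.sum(axis=0)
    total = np.where(obs, d, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        score = np.where(n_used > 0, total / (2.0 * np.maximum(n_used, 1)), np.nan)
    if strict:
        score = np.where(n_used == arm.n_alleles, score, np.nan)
    return pd.DataFrame(
        {"sample": arm.sample_ids, "score": score, "n_snps_used": n_used}
    )


def grs_distribution(
    grs: pd.DataFrame, panel: SamplePanel, level: GroupLevel = "super"
) -> pd.DataFrame:
    """Five-number summary of GRS per group plus the pooled global median.

    Quartiles use linear interpolation between order statistics; the
    convention is recorded in the ``quartile_method`` column so box plots are
    reproducible. Groups with no scored samples are omitted with a warning.
    """
    import logging

    scores = grs.set_index("sample")["score"]
    global_median = float(np.nanmedian(scores.to_numpy()))
    rows = []
    for group, samples in sorted(panel.groups(level).items()):
        vals = scores.loc[[s for s in samples if s in scores.index]].dropna()
        if vals.empty:
            logging.getLogger(__name__).warning("group %s has no scores; omitted", group)
            continue
        q1, med, q3 = np.percentile(vals, [25, 50, 75], method=QUARTILE_METHOD)
        rows.append(
            {
                "group": group,
                "n": len(vals),
                "min": vals.min(),
                "q1": q1,
                "median": med,
                "q3": q3,
                "max": vals.max(),
                "global_median": global_median,
                "quartile_method": QUARTILE_METHOD,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class SubsetRule:
    """One named subset: how many alleles to draw per discovery ancestry,
    optionally on top of (nesting) a previously built subset."""

    name: str
    counts: Mapping[str, int]
    include: str | None = None


@dataclass
class BiasSubsetSpec:
    rules: list[SubsetRule]
    seed: int = 0


def default_bias_spec(seed: int = 0) -> BiasSubsetSpec:
    """The standard three-subset design for a 62-EUR + 2-EAS risk table:
    Set1 = 2 EAS + 8 random EUR; Set2 = Set1 plus 5 more EUR (15 total);
    Set3 = 10 random EUR only."""
    return BiasSubsetSpec(
        rules=[
            SubsetRule("Set1", {"EAS": 2, "EUR": 8}),
            SubsetRule("Set2", {"EUR": 5}, include="Set1"),
            SubsetRule("Set3", {"EUR": 10}),
        ],
        seed=seed,
    )


def bias_subsets(
    risk: Sequence[RiskAllele], spec: BiasSubsetSpec
) -> dict[str, list[RiskAllele]]:
    """Draw the named risk-allele subsets, without replacement within each
    ancestry stratum, deterministically from ``spec.seed``.

    A rule with ``include`` nests the named earlier subset and draws its own
    counts from alleles not already taken there. Requesting more alleles of an
    ancestry than exist is an error.
    """
    rng = np.random.default_rng(spec.seed)
    by_ancestry: dict[str, list[RiskAllele]] = {}
    for ra in risk:
        if ra.ancestry is None:
            raise ValueError(f"{ra.rsid}: ancestry label required for bias subsets")
        by_ancestry.setdefault(ra.ancestry, []).append(ra)
    out: dict[str, list[RiskAllele]] = {}
    for rule in spec.rules:
        chosen: list[RiskAllele] = []
        if rule.include is not None:
            if rule.include not in out:
                raise ValueError(f"{rule.name}: unknown base subset {rule.include!r}")
            chosen.extend(out[rule.include])
        taken = {ra.rsid for ra in chosen}
        for ancestry, k in rule.counts.items():
            pool = [ra for ra in by_ancestry.get(ancestry, []) if ra.rsid not in taken]
            if k > len(pool):
                raise ValueError(
                    f"{rule.name}: requested {k} {ancestry} alleles, only "
                    f"{len(pool)} available"
                )
            picks = rng.choice(len(pool), size=k, replace=False)
            chosen.extend(pool[i] for i in sorted(picks))
        out[rule.name] = chosen
    return out


def subset_medians(
    subsets: Mapping[str, Sequence[RiskAllele]],
    arm: AlignedRiskMatrix,
    panel: SamplePanel,
    groups: Sequence[str],
    level: GroupLevel = "super",
) -> pd.DataFrame:
    """Median GRS per (subset, group), recomputing scores on each subset.

    The returned table has one row per subset plus an ``all`` row over the
    full aligned set — the layout used to compare EUR vs EAS medians across
    allele subsets. An empty subset gets NaN medians and a flag.
    """
    level_groups = panel.groups(level)
    unknown = [g for g in groups if g not in level_groups]
    if unknown:
        raise ValueError(f"unknown group(s) at level {level!r}: {unknown}")
    rows = []
    named = dict(subsets)
    named["all"] = list(arm.risk_alleles)
    for name, alleles in named.items():
        row: dict[str, object] = {"subset": name, "n_alleles": len(alleles)}
        if not alleles:
            for g in groups:
                row[g] = np.nan
            row["empty"] = True
            rows.append(row)
            continue
        sub_arm = arm.subset(alleles)
        grs = genetic_risk_score(sub_arm).set_index("sample")["score"]
        for g in groups:
            vals = grs.loc[[s for s in level_groups[g] if s in grs.index]].dropna()
            row[g] = float(np.median(vals)) if len(vals) else np.nan
        row["empty"] = False
        rows.append(row)
    return pd.DataFrame(rows)


def plot_grs_boxes(
    grs: pd.DataFrame, panel: SamplePanel, path, level: GroupLevel = "super"
) -> None:
    """Box plot of GRS per group with a dotted line at the pooled global
    median, mirroring the standard presentation of stratified risk scores."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    scores = grs.set_index("sample")["score"]
    groups = sorted(panel.groups(level).items())
    data = [
        scores.loc[[s for s in samples if s in scores.index]].dropna().to_numpy()
        for _, samples in groups
    ]
    fig, ax = plt.subplots(figsize=(1.2 * len(groups) + 2, 4))
    ax.boxplot(data, tick_labels=[g for g, _ in groups])
    ax.axhline(float(np.nanmedian(scores)), linestyle=":", color="grey",
               label="global normal median")
    ax.set_ylabel("genetic risk score")
    ax.legend(loc="upper right", fontsize="small")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
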