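"""Fisher's-exact enrichment/depletion of risk alleles per population.

Each population's risk-allele count is compared against the pooled global
reference ("global normal") in a 2×2 table of risk vs non-risk chromosome
counts. Two-sided Fisher p-values are corrected for multiple testing over
the whole allele × population grid and turned into a signed score:

    score = -log10(p_adj)   if significant and pop freq > reference freq
          = +log10(p_adj)   if significant and pop freq < reference freq
          = 0               otherwise,

so positive = enriched, negative = depleted, zero = no significant change.
Population score-vectors are then clustered hierarchically and rendered as
a diverging heatmap (red = enriched, blue = depleted).

The two-sided Fisher p uses the point-probability rule — the sum of all
hypergeometric outcomes whose probability does not exceed that of the
observed table — evaluated in log space via gammaln, which keeps dense
grids and exhaustive sweeps fast.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.cluster.hierarchy import leaves_list, linkage, to_tree

from .popio import AlignedRiskMatrix, GroupLevel, SamplePanel, group_counts

SCORE_CAP = 320.0  # |score| cap when p_adj underflows to 0

#: Relative tolerance for the "probability not exceeding the observed
#: table's" comparison, guarding against floating-point near-ties.
_TIE_RTOL = 1e-7


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Chromosome counts: (a, b) risk/non-risk in the population,
    (c, d) risk/non-risk in the reference."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")


def fisher_exact(table: ContingencyTable2x2 | tuple[int, int, int, int]) -> float:
    """Two-sided Fisher's exact p-value for a 2×2 table.

    Point-probability convention: p is the sum of hypergeometric
    probabilities of all tables (same margins) at most as probable as the
    observed one. Returns a value in (0, 1].
    """
    if isinstance(table, ContingencyTable2x2):
        a, b, c, d = table.a, table.b, table.c, table.d
    else:
        a, b, c, d = table
        if min(a, b, c, d) < 0:
            raise ValueError("contingency counts must be non-negative")
    r1, r2 = a + b, c + d
    k = a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or k == 0 or k == n:
        return 1.0  # degenerate margin: only one table possible
    lo, hi = max(0, k - r2), min(r1, k)
    support = np.arange(lo, hi + 1)

    def log_comb(n_, k_):
        return gammaln(n_ + 1) - gammaln(k_ + 1) - gammaln(n_ - k_ + 1)

    logpmf = log_comb(r1, support) + log_comb(r2, k - support) - log_comb(n, k)
    log_obs = logpmf[a - lo]
    mask = logpmf <= log_obs + np.log1p(_TIE_RTOL)
    # sum in probability space with the common factor removed for stability
    p = float(np.exp(logpmf[mask] - log_obs).sum() * np.exp(log_obs))
    return min(p, 1.0)


def allele_count_table(
    freq: pd.DataFrame, variant: int, group: str, reference_group: str
) -> ContingencyTable2x2:
    """Build the 2×2 risk/non-risk table for one variant from a long-form
    frequency table whose ``alt_count`` column counts the RISK allele
    (i.e. built from risk-aligned dosages)."""

    def counts(g: str) -> tuple[int, int]:
        sel = freq[(freq["variant"] == variant) & (freq["group"] == g)]
        if sel.empty:
            raise KeyError(f"group {g!r} absent from frequency table")
        n_chrom = int(sel["n_chromosomes"].iloc[0])
        if n_chrom == 0:
            raise ValueError(f"group {g!r} has zero chromosomes at variant {variant}")
        return int(sel["alt_count"].iloc[0]), n_chrom

    risk_pop, n_pop = counts(group)
    risk_ref, n_ref = counts(reference_group)
    return ContingencyTable2x2(
        a=risk_pop, b=n_pop - risk_pop, c=risk_ref, d=n_ref - risk_ref
    )


def adjust_pvalues(
    pvals: Sequence[float], method: Literal["BH", "bonferroni"] = "BH"
) -> np.ndarray:
    """Multiple-testing adjustment over one family of tests."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(pvals, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    key = {"BH": "fdr_bh", "bonferroni": "bonferroni"}[method]
    return multipletests(p, method=key)[1]


def signed_score(
    p_adj: float, pop_freq: float, ref_freq: float, alpha: float = 0.05
) -> float:
    """Signed −log10 adjusted p; zero when not significant at ``alpha``."""
    import logging

    if p_adj > alpha:
        return 0.0
    if pop_freq == ref_freq:
        logging.getLogger(__name__).warning(
            "significant p_adj=%g with exact frequency tie; score set to 0", p_adj
        )
        return 0.0
    if p_adj == 0.0:
        magnitude = SCORE_CAP
    else:
        magnitude = min(-np.log10(p_adj), SCORE_CAP)
    return magnitude if pop_freq > ref_freq else -magnitude


@dataclass
class EnrichmentMatrix:
    """Long-form per-(allele, group) results plus the pivoted score matrix."""

    table: pd.DataFrame  # rsid, group, a, b, c, d, pop_freq, ref_freq, p, p_adj, score
    scores: pd.DataFrame  # rows = rsid, columns = group
    no_change: list[str]  # rsids with all-zero scores (excluded from plots)
    metadata: dict = field(default_factory=dict)


def risk_frequencies(
    arm: AlignedRiskMatrix, panel: SamplePanel, level: GroupLevel
) -> pd.DataFrame:
    """Long-form frequency table of RISK-allele counts per group (same
    columns as :func:`vitipop.popio.allele_frequencies`)."""
    frames = []
    index = {s: i for i, s in enumerate(arm.sample_ids)}
    for group, samples in sorted(panel.groups(level).items()):
        idx = np.array([index[s] for s in samples], dtype=np.intp)
        cnt, n_chrom = group_counts(arm.dosages, idx)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(n_chrom > 0, cnt / np.maximum(n_chrom, 1), np.nan)
        frames.append(
            pd.DataFrame(
                {
                    "variant": np.arange(arm.n_alleles),
                    "id": [ra.rsid for ra in arm.risk_alleles],
                    "group": group,
                    "n_chromosomes": n_chrom,
                    "alt_count": cnt,
                    "alt_freq": f,
                    "maf": np.minimum(f, 1 - f),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def enrichment_matrix(
    arm: AlignedRiskMatrix,
    panel: SamplePanel,
    level: GroupLevel = "super",
    adjust: Literal["BH", "bonferroni"] = "BH",
    alpha: float = 0.05,
    exclude_self: bool = False,
) -> EnrichmentMatrix:
    """Full enrichment pipeline: count table → Fisher → adjust → signed score
    for every (risk allele, group) cell.

    The reference is the pooled global cohort; by default it *includes* the
    tested population's samples (each group is compared against the whole
    cohort), ``exclude_self=True`` removes them. The adjustment family is the
    entire allele × group matrix. Alleles significant nowhere are listed in
    ``no_change`` and dropped from plots.
    """
    index = {s: i for i, s in enumerate(arm.sample_ids)}
    groups = sorted(panel.groups(level).items())
    all_idx = np.arange(len(arm.sample_ids))
    glob_cnt, glob_n = group_counts(arm.dosages, all_idx)

    rows = []
    for group, samples in groups:
        idx = np.array([index[s] for s in samples], dtype=np.intp)
        cnt, n_chrom = group_counts(arm.dosages, idx)
        if exclude_self:
            ref_cnt, ref_n = glob_cnt - cnt, glob_n - n_chrom
        else:
            ref_cnt, ref_n = glob_cnt, glob_n
        for i, ra in enumerate(arm.risk_alleles):
            a, b = int(cnt[i]), int(n_chrom[i] - cnt[i])
            c, d = int(ref_cnt[i]), int(ref_n[i] - ref_cnt[i])
            if n_chrom[i] == 0 or ref_n[i] == 0:
                raise ValueError(f"zero chromosomes for {ra.rsid} in {group}")
            rows.append(
                {
                    "rsid": ra.rsid,
                    "group": group,
                    "a": a, "b": b, "c": c, "d": d,
                    "pop_freq": a / (a + b),
                    "ref_freq": c / (c + d),
                    "p": fisher_exact((a, b, c, d)),
                }
            )
    table = pd.DataFrame(rows)
    table["p_adj"] = adjust_pvalues(table["p"].to_numpy(), method=adjust)
    table["score"] = [
        signed_score(r.p_adj, r.pop_freq, r.ref_freq, alpha=alpha)
        for r in table.itertuples()
    ]
    table["direction"] = np.sign(table["pop_freq"] - table["ref_freq"]).astype(int)
    rsids = [ra.rsid for ra in arm.risk_alleles]
    scores = (
        table.pivot(index="rsid", columns="group", values="score")
        .reindex(rsids)
    )
    no_change = [r for r in rsids if (scores.loc[r] == 0).all()]
    return EnrichmentMatrix(
        table=table,
        scores=scores,
        no_change=no_change,
        metadata={
            "adjust": adjust,
            "alpha": alpha,
            "level": level,
            "reference": "global pooled"
            + (" (excluding tested group)" if exclude_self else " (including tested group)"),
        },
    )


def cluster_populations(
    em: EnrichmentMatrix,
    method: str = "average",
    metric: str = "euclidean",
) -> tuple[list[str], np.ndarray]:
    """Agglomerative clustering of population score-vectors.

    Returns the leaf-ordered group names and the scipy linkage matrix.
    Average linkage on Euclidean distance by default; both recorded by the
    caller via the returned objects. Deterministic (scipy linkage is)."""
    import logging

    if em.scores.shape[1] < 2:
        raise ValueError("need at least 2 groups to cluster")
    X = em.scores.to_numpy().T  # groups × alleles
    if np.allclose(X, X[0]):
        logging.getLogger(__name__).warning(
            "constant score matrix; cluster order is arbitrary but deterministic"
        )
    Z = linkage(X, method=method, metric=metric)
    order = [em.scores.columns[i] for i in leaves_list(Z)]
    return order, Z


def outermost_group(em: EnrichmentMatrix, **kwargs) -> str | None:
    """The group split off alone at the root of the dendrogram (the
    "outgroup"), or None when the root splits into two multi-group clades."""
    _, Z = cluster_populations(em, **kwargs)
    root = to_tree(Z)
    for side in (root.left, root.right):
        if side.is_leaf():
            return str(em.scores.columns[side.id])
    left = root.left.pre_order()
    right = root.right.pre_order()
    if len(left) == 1:
        return str(em.scores.columns[left[0]])
    if len(right) == 1:
        return str(em.scores.columns[right[0]])
    return None


def render_heatmap(em: EnrichmentMatrix, path, drop_no_change: bool = True) -> None:
    """Clustered diverging heatmap of signed enrichment scores
    (red = enriched, blue = depleted, white = no significant change)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import seaborn as sns

    scores = em.scores
    if drop_no_change and em.no_change and len(em.no_change) < len(scores):
        scores = scores.drop(index=em.no_change)
    if scores.shape[1] >= 2 and not np.allclose(scores.to_numpy(), 0):
        order, _ = cluster_populations(
            EnrichmentMatrix(em.table, scores, [], em.metadata)
        )
        scores = scores[order]
        if scores.shape[0] >= 2:
            Zr = linkage(scores.to_numpy(), method="average", metric="euclidean")
            scores = scores.iloc[leaves_list(Zr)]
    vmax = max(float(np.abs(scores.to_numpy()).max()), 1e-6)
    fig, ax = plt.subplots(
        figsize=(0.6 * scores.shape[1] + 3, 0.25 * scores.shape[0] + 2)
    )
    sns.heatmap(
        scores, cmap="RdBu_r", center=0, vmin=-vmax, vmax=vmax, ax=ax,
        cbar_kws={"label": "signed -log10 adjusted p"},
    )
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
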