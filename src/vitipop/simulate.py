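"""Balding-Nichols cohort simulator with known ground truth.

Emulates a 1000-Genomes-like multi-population cohort: for each biallelic
SNP an ancestral allele frequency p is drawn, then each population's
frequency is drawn from Beta(p(1-F)/F, (1-p)(1-F)/F) — the Balding-Nichols
model, whose differentiation parameter F is exactly the Fst the downstream
estimators are asked to recover. Genotypes are Hardy-Weinberg draws
Binomial(2, p_pop) per sample. Designated "risk" loci can be given planted
frequency shifts in chosen populations so enrichment/prioritisation power
is testable against known truth.

All randomness flows through one ``numpy.random.Generator`` seeded from
``SimulationConfig.seed``, so cohorts (and the VCFs written from them) are
byte-identical across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .popio import GenotypeMatrix, Locus, RiskAllele, SamplePanel

SHIFT_CLAMP = (0.01, 0.99)  # planted loci stay polymorphic


@dataclass(frozen=True)
class PopulationSpec:
    name: str
    super_population: str
    n_samples: int

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError(f"{self.name}: n_samples must be >= 1")


@dataclass
class SimulationConfig:
    """Cohort layout and generative parameters.

    ``ancestral_freq`` is either a (low, high) tuple for uniform draws or an
    explicit per-SNP frequency sequence of length ``n_snps``.
    ``fst`` maps population name -> Balding-Nichols F (0 <= F < 1); a single
    float applies to every population. ``planted_shifts`` is a list of
    (snp_index, population, delta_freq); the shifted frequency is clamped to
    [0.01, 0.99].
    """

    populations: list[PopulationSpec]
    n_snps: int
    ancestral_freq: tuple[float, float] | Sequence[float] = (0.1, 0.9)
    fst: float | dict[str, float] = 0.1
    planted_shifts: list[tuple[int, str, float]] = field(default_factory=list)
    seed: int = 0
    chrom: str = "chr1"

    def __post_init__(self) -> None:
        if not self.populations:
            raise ValueError("population list is empty")
        names = [p.name for p in self.populations]
        if len(set(names)) != len(names):
            raise ValueError("population names must be unique")
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        for name, f in self.fst_by_population().items():
            if not (0 <= f < 1):
                raise ValueError(f"F for {name} must satisfy 0 <= F < 1, got {f}")
        for idx, pop, _ in self.planted_shifts:
            if not (0 <= idx < self.n_snps):
                raise ValueError(f"planted shift SNP index {idx} out of range")
            if pop not in names:
                raise ValueError(f"planted shift population {pop!r} unknown")

    def fst_by_population(self) -> dict[str, float]:
        if isinstance(self.fst, dict):
            return {p.name: self.fst[p.name] for p in self.populations}
        return {p.name: float(self.fst) for p in self.populations}


@dataclass
class TruthTable:
    """Ground truth per (SNP, population): the realised frequencies the
    genotypes were drawn from, plus planted-shift flags."""

    ancestral_freq: np.ndarray  # (n_snps,)
    pop_freq: pd.DataFrame  # long form: snp, population, freq, shifted
    planted_snps: set[int]

    def freq_of(self, snp: int, population: str) -> float:
        sel = self.pop_freq[
            (self.pop_freq["snp"] == snp) & (self.pop_freq["population"] == population)
        ]
        return float(sel["freq"].iloc[0])

    def freq_matrix(self) -> pd.DataFrame:
        """SNP × population frequency matrix."""
        return self.pop_freq.pivot(index="snp", columns="population", values="freq")


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[GenotypeMatrix, SamplePanel, TruthTable]:
    """Draw a multi-population cohort under the Balding-Nichols model.

    Returns the genotype matrix (ALT dosages, no missingness), the sample
    panel, and the :class:`TruthTable` of realised per-population
    frequencies. Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_snps

    if isinstance(config.ancestral_freq, tuple) and len(config.ancestral_freq) == 2 \
            and np.isscalar(config.ancestral_freq[0]):
        low, high = config.ancestral_freq
        p_anc = rng.uniform(low, high, size=n)
    else:
        p_anc = np.asarray(config.ancestral_freq, dtype=float)
        if p_anc.shape != (n,):
            raise ValueError("ancestral_freq sequence must have length n_snps")
        if ((p_anc < 0) | (p_anc > 1)).any():
            raise ValueError("ancestral frequencies must lie in [0, 1]")

    fst = config.fst_by_population()
    pop_freqs: dict[str, np.ndarray] = {}
    for spec in config.populations:
        f = fst[spec.name]
        if f == 0:
            # degenerate limit: no drift, population frequency = ancestral
            pop_freqs[spec.name] = p_anc.copy()
        else:
            scale = (1 - f) / f
            pop_freqs[spec.name] = rng.beta(p_anc * scale, (1 - p_anc) * scale)

    planted: set[int] = set()
    shifted_flags = {spec.name: np.zeros(n, dtype=bool) for spec in config.populations}
    for idx, pop, delta in config.planted_shifts:
        pop_freqs[pop][idx] = np.clip(pop_freqs[pop][idx] + delta, *SHIFT_CLAMP)
        shifted_flags[pop][idx] = True
        planted.add(idx)

    cols: list[np.ndarray] = []
    sample_ids: list[str] = []
    entries: dict[str, tuple[str, str]] = {}
    for spec in config.populations:
        p = pop_freqs[spec.name]
        # HWE within population: dosage ~ Binomial(2, p_pop) per sample
        g = rng.binomial(2, p[:, None], size=(n, spec.n_samples)).astype(np.int16)
        cols.append(g)
        for j in range(spec.n_samples):
            sid = f"{spec.name}_{j:04d}"
            sample_ids.append(sid)
            entries[sid] = (spec.name, spec.super_population)

    loci = [
        Locus(chrom=config.chrom, pos=1 + 1000 * i, id=f"snp{i}", ref="A", alt="G")
        for i in range(n)
    ]
    gm = GenotypeMatrix(
        loci=loci, dosages=np.hstack(cols), sample_ids=sample_ids
    )
    panel = SamplePanel(entries)
    truth = TruthTable(
        ancestral_freq=p_anc,
        pop_freq=pd.DataFrame(
            [
                {
                    "snp": i,
                    "population": spec.name,
                    "freq": pop_freqs[spec.name][i],
                    "shifted": bool(shifted_flags[spec.name][i]),
                }
                for spec in config.populations
                for i in range(n)
            ]
        ),
        planted_snps=planted,
    )
    return gm, panel, truth


def concat_cohorts(
    a: GenotypeMatrix, b: GenotypeMatrix
) -> GenotypeMatrix:
    """Stack the variants of two cohorts simulated over the same samples.

    Useful for mixed designs, e.g. a neutral background at one F plus a
    block of planted loci drawn under different parameters. The two parts
    must use distinct chromosomes (or non-overlapping positions) so the
    sorted-loci invariant holds.
    """
    if a.sample_ids != b.sample_ids:
        raise ValueError("cohorts must share the same samples in the same order")
    loci = a.loci + b.loci
    if sorted(loci, key=lambda l: (l.chrom, l.pos)) != loci:
        raise ValueError("concatenated loci are not sorted; use distinct chromosomes")
    return GenotypeMatrix(
        loci=loci,
        dosages=np.vstack([a.dosages, b.dosages]),
        sample_ids=list(a.sample_ids),
    )


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write a minimal VCF v4.2 (GT only) that round-trips through
    :func:`vitipop.popio.read_vcf`."""
    gt_of = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chroms = {l.chrom for l in gm.loci}
        for c in sorted(chroms):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.sample_ids)
            + "\n"
        )
        for locus, row in zip(gm.loci, gm.dosages):
            info = f"AA={locus.ancestral}" if locus.ancestral else "."
            gts = "\t".join(gt_of[int(d)] for d in row)
            fh.write(
                f"{locus.chrom}\t{locus.pos}\t{locus.id}\t{locus.ref}\t"
                f"{locus.alt}\t.\tPASS\t{info}\tGT\t{gts}\n"
            )


def write_panel(panel: SamplePanel, path) -> None:
    """Write a 1KGP-dialect panel TSV (sample, pop, super_pop)."""
    with open(path, "w") as fh:
        fh.write("sample\tpop\tsuper_pop\n")
        for sample, (pop, sup) in panel.entries.items():
            fh.write(f"{sample}\t{pop}\t{sup}\n")


def write_truth(truth: TruthTable, path) -> None:
    truth.pop_freq.to_csv(path, sep="\t", index=False, float_format="%.6g")


def make_risk_table(
    gm: GenotypeMatrix,
    snp_indices: Sequence[int],
    ancestry_labels: Sequence[str],
    seed: int = 0,
    risk_is_ref: Sequence[int] = (),
) -> list[RiskAllele]:
    """Designate simulated SNPs as GWAS risk alleles.

    By default the risk allele is ALT; indices listed in ``risk_is_ref`` get
    REF as the risk allele instead (exercising the dosage-flip path).
    Synthetic odds ratios are drawn uniformly in [1.0, 1.5], matching the
    modest effect sizes typical of autoimmune-disease GWAS hits.
    """
    if len(snp_indices) != len(ancestry_labels):
        raise ValueError("snp_indices and ancestry_labels must have equal length")
    for i in snp_indices:
        if not (0 <= i < gm.n_variants):
            raise IndexError(f"SNP index {i} out of range")
    rng = np.random.default_rng(seed)
    flip = set(risk_is_ref)
    out = []
    for i, anc in zip(snp_indices, ancestry_labels):
        locus = gm.loci[i]
        ref_is_risk = i in flip
        out.append(
            RiskAllele(
                rsid=locus.id,
                chrom=locus.chrom,
                pos=locus.pos,
                risk_allele=locus.ref if ref_is_risk else locus.alt,
                other_allele=locus.alt if ref_is_risk else locus.ref,
                odds_ratio=round(float(rng.uniform(1.0, 1.5)), 3),
                ancestry=anc,
            )
        )
    return out


def write_risk_table(risk: Sequence[RiskAllele], path) -> None:
    with open(path, "w") as fh:
        fh.write("rsid\tchrom\tpos\trisk_allele\tother_allele\todds_ratio\tancestry\tgene\n")
        for ra in risk:
            fh.write(
                f"{ra.rsid}\t{ra.chrom}\t{ra.pos}\t{ra.risk_allele}\t{ra.other_allele}\t"
                f"{'' if ra.odds_ratio is None else ra.odds_ratio}\t"
                f"{ra.ancestry or ''}\t{ra.gene or ''}\n"
            )


def kgp_like_populations(n_per_pop: int = 100) -> list[PopulationSpec]:
    """A seven-super-population layout echoing 1KGP plus an Indian cohort:
    AFR, AMR1, AMR2, EAS, EUR, SAS, IND (one sub-population each by default)."""
    return [
        PopulationSpec("YRI", "AFR", n_per_pop),
        PopulationSpec("CLM", "AMR1", n_per_pop),
        PopulationSpec("PEL", "AMR2", n_per_pop),
        PopulationSpec("CHB", "EAS", n_per_pop),
        PopulationSpec("CEU", "EUR", n_per_pop),
        PopulationSpec("GIH", "SAS", n_per_pop),
        PopulationSpec("IND", "IND", n_per_pop),
    ]
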