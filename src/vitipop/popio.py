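"""Reading cohort data and computing population allele frequencies.

This module owns the in-memory containers shared by the whole pipeline:

* :class:`GenotypeMatrix` — biallelic variant × sample dosage matrix read
  from a multi-sample VCF (GT field only; dosage is the ALT-allele count,
  ``-1`` marks a missing or half call).
* :class:`SamplePanel` — the 1000-Genomes-style two-level grouping of
  samples into sub-populations and super-populations, with the optional
  ancestry-based split of the Admixed Americans into AMR1 (CLM, PUR) and
  AMR2 (MXL, PEL).
* :class:`RiskAllele` / :class:`AlignedRiskMatrix` — a GWAS risk-allele
  table and its alignment onto VCF loci, flipping dosages where the risk
  allele is the VCF REF allele.
* allele/genotype counting for any grouping level, including the pooled
  "global" reference every population is later compared against.

Coordinates follow the VCF convention (1-based positions); all array
indices are 0-based.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1

GroupLevel = Literal["sub", "super", "global"]

#: 1000 Genomes Phase-3 sub-population → super-population map, used as a
#: fallback when a panel file lacks the super_pop column.
KGP_SUB_TO_SUPER: dict[str, str] = {
    # African
    "YRI": "AFR", "LWK": "AFR", "GWD": "AFR", "MSL": "AFR", "ESN": "AFR",
    "ASW": "AFR", "ACB": "AFR",
    # Admixed American
    "MXL": "AMR", "PUR": "AMR", "CLM": "AMR", "PEL": "AMR",
    # East Asian
    "CHB": "EAS", "JPT": "EAS", "CHS": "EAS", "CDX": "EAS", "KHV": "EAS",
    # European
    "CEU": "EUR", "TSI": "EUR", "FIN": "EUR", "GBR": "EUR", "IBS": "EUR",
    # South Asian
    "GIH": "SAS", "PJL": "SAS", "BEB": "SAS", "STU": "SAS", "ITU": "SAS",
}

#: Ancestry-based recoding of the Admixed American sub-populations:
#: AMR1 is European-derived (CLM, PUR), AMR2 is Latino (MXL, PEL).
AMR_SPLIT: dict[str, str] = {"CLM": "AMR1", "PUR": "AMR1", "MXL": "AMR2", "PEL": "AMR2"}

GLOBAL_GROUP = "GLOBAL"


@dataclass(frozen=True)
class Locus:
    """One biallelic site: VCF CHROM/POS/ID/REF/ALT plus optional ancestral allele."""

    chrom: str
    pos: int  # 1-based
    id: str
    ref: str
    alt: str
    ancestral: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")


@dataclass(frozen=True)
class RiskAllele:
    """A GWAS-reported disease risk variant.

    The risk allele may correspond to either REF or ALT of the cohort VCF;
    :func:`align_risk_alleles` resolves the orientation.
    """

    rsid: str
    chrom: str
    pos: int
    risk_allele: str
    other_allele: str
    odds_ratio: float | None = None
    ancestry: str | None = None
    gene: str | None = None

    def __post_init__(self) -> None:
        if self.risk_allele == self.other_allele:
            raise ValueError(f"{self.rsid}: risk allele equals other allele")
        if self.pos < 1:
            raise ValueError(f"{self.rsid}: position must be >= 1")


@dataclass
class GenotypeMatrix:
    """Biallelic variant × sample ALT-dosage matrix with locus metadata."""

    loci: list[Locus]
    dosages: np.ndarray  # (n_variants, n_samples), int8/int16; -1 = missing
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages)
        if self.dosages.shape != (len(self.loci), len(self.sample_ids)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.loci)} loci x {len(self.sample_ids)} samples"
            )
        valid = np.isin(self.dosages, (MISSING, 0, 1, 2))
        if not valid.all():
            bad = np.unique(self.dosages[~valid])
            raise ValueError(f"dosages must be in {{-1,0,1,2}}; found {bad}")

    @property
    def n_variants(self) -> int:
        return len(self.loci)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sample_indices(self, samples: Iterable[str]) -> np.ndarray:
        index = {s: i for i, s in enumerate(self.sample_ids)}
        return np.array([index[s] for s in samples], dtype=np.intp)


class SamplePanel:
    """Sample → (sub-population, super-population) mapping.

    Parameters
    ----------
    entries
        Mapping from sample id to ``(population, super_population)``.
    amr_split
        When True, Admixed American sub-populations are recoded at the
        super-population level: CLM and PUR become AMR1 (European derived),
        MXL and PEL become AMR2 (Latino).
    """

    def __init__(self, entries: Mapping[str, tuple[str, str]], amr_split: bool = False):
        if not entries:
            raise ValueError("panel is empty")
        self.entries: dict[str, tuple[str, str]] = dict(entries)
        pop_to_super: dict[str, str] = {}
        for sample, (pop, sup) in self.entries.items():
            if pop in pop_to_super and pop_to_super[pop] != sup:
                raise ValueError(
                    f"population {pop} maps to both {pop_to_super[pop]} and {sup}"
                )
            pop_to_super[pop] = sup
        if amr_split:
            amr_pops = {p for p, s in pop_to_super.items() if s == "AMR"}
            unknown = amr_pops - set(AMR_SPLIT)
            if unknown:
                raise ValueError(
                    f"cannot split AMR: unknown sub-population(s) {sorted(unknown)}"
                )
            for p in amr_pops:
                pop_to_super[p] = AMR_SPLIT[p]
            self.entries = {
                s: (pop, pop_to_super[pop]) for s, (pop, _) in self.entries.items()
            }
        self.amr_split = amr_split
        self.pop_to_super = pop_to_super

    @property
    def samples(self) -> list[str]:
        return list(self.entries)

    def population_of(self, sample: str) -> str:
        return self.entries[sample][0]

    def super_population_of(self, sample: str) -> str:
        return self.entries[sample][1]

    def groups(self, level: GroupLevel) -> dict[str, list[str]]:
        """Sample lists per group at the requested level.

        ``global`` yields a single pooled group containing every sample.
        """
        if level == "global":
            return {GLOBAL_GROUP: list(self.entries)}
        idx = 0 if level == "sub" else 1
        if level not in ("sub", "super"):
            raise ValueError(f"unknown grouping level {level!r}")
        out: dict[str, list[str]] = {}
        for sample, labels in self.entries.items():
            out.setdefault(labels[idx], []).append(sample)
        return out

    def __len__(self) -> int:
        return len(self.entries)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, SamplePanel) and self.entries == other.entries


@dataclass
class AlignedRiskMatrix:
    """Risk-allele dosages X_i per sample, aligned onto VCF loci.

    ``dosages[i, j]`` counts copies of the *risk* allele of ``risk_alleles[i]``
    carried by sample ``j`` (missing = -1). ``flipped[i]`` is True when the
    risk allele is the VCF REF allele, in which case the ALT dosage d was
    transformed to 2 - d. Risk alleles that could not be matched are listed
    in ``dropped`` with a reason.
    """

    risk_alleles: list[RiskAllele]
    dosages: np.ndarray  # (n_risk, n_samples)
    sample_ids: list[str]
    loci: list[Locus]
    flipped: np.ndarray  # (n_risk,) bool
    dropped: list[tuple[RiskAllele, str]] = field(default_factory=list)

    @property
    def n_alleles(self) -> int:
        return len(self.risk_alleles)

    def subset(self, alleles: Sequence[RiskAllele]) -> "AlignedRiskMatrix":
        """Restrict to the given risk alleles (matched by rsid), keeping order."""
        index = {ra.rsid: i for i, ra in enumerate(self.risk_alleles)}
        rows = [index[a.rsid] for a in alleles]
        sel = np.array(rows, dtype=np.intp)
        return AlignedRiskMatrix(
            risk_alleles=[self.risk_alleles[i] for i in rows],
            dosages=self.dosages[sel],
            sample_ids=self.sample_ids,
            loci=[self.loci[i] for i in rows],
            flipped=self.flipped[sel],
            dropped=[],
        )


def read_vcf(path, region: str | None = None) -> GenotypeMatrix:
    """Read a multi-sample VCF into a :class:`GenotypeMatrix`.

    Multiallelic records are excluded (their count is logged); genotypes
    ``./.`` and half calls are recorded as missing. ``region`` is an optional
    ``chrom`` or ``chrom:start-end`` filter (1-based, inclusive) applied while
    streaming, so no index is required.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    want_chrom = want_lo = want_hi = None
    if region:
        if ":" in region:
            want_chrom, span = region.split(":", 1)
            lo, hi = span.split("-", 1)
            want_lo, want_hi = int(lo), int(hi)
        else:
            want_chrom = region

    loci: list[Locus] = []
    rows: list[np.ndarray] = []
    n_multi = 0
    for var in vcf:
        if want_chrom is not None and var.CHROM != want_chrom:
            continue
        if want_lo is not None and not (want_lo <= var.POS <= want_hi):
            continue
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        anc = var.INFO.get("AA")
        gts = np.asarray(var.genotype.array(), dtype=np.int16)  # (n, ploidy+1)
        alleles = gts[:, :2]
        dos = alleles.sum(axis=1).astype(np.int16)
        dos[(alleles < 0).any(axis=1)] = MISSING  # ./., half calls
        loci.append(
            Locus(
                chrom=var.CHROM,
                pos=var.POS,
                id=var.ID or f"{var.CHROM}:{var.POS}",
                ref=var.REF,
                alt=var.ALT[0],
                ancestral=str(anc) if anc is not None else None,
            )
        )
        rows.append(dos)
    vcf.close()
    if n_multi:
        logger.info("read_vcf(%s): excluded %d multiallelic record(s)", path, n_multi)
    dosages = (
        np.vstack(rows) if rows else np.empty((0, len(samples)), dtype=np.int16)
    )
    return GenotypeMatrix(loci=loci, dosages=dosages, sample_ids=samples)


def read_panel(path, amr_split: bool = False) -> SamplePanel:
    """Read a 1KGP-style panel file (TSV: sample, pop, super_pop).

    A missing/empty super_pop column is filled from the built-in 1KGP
    sub→super map; an unmapped sub-population is an error in that case.
    """
    df = pd.read_csv(path, sep=r"\s+", dtype=str)
    df.columns = [c.lower() for c in df.columns]
    if "sample" not in df.columns or "pop" not in df.columns:
        raise ValueError(f"panel {path} must have 'sample' and 'pop' columns")
    dup = df["sample"][df["sample"].duplicated()]
    if not dup.empty:
        raise ValueError(f"duplicate sample id(s) in panel: {sorted(set(dup))}")
    entries: dict[str, tuple[str, str]] = {}
    for _, row in df.iterrows():
        pop = row["pop"]
        sup = row.get("super_pop")
        if sup is None or (isinstance(sup, float) and np.isnan(sup)) or sup == "":
            if pop not in KGP_SUB_TO_SUPER:
                raise ValueError(
                    f"panel {path}: no super_pop for sample {row['sample']} and "
                    f"sub-population {pop!r} is not a known 1KGP population"
                )
            sup = KGP_SUB_TO_SUPER[pop]
        entries[row["sample"]] = (pop, str(sup))
    return SamplePanel(entries, amr_split=amr_split)


RISK_TABLE_COLUMNS = ("rsid", "chrom", "pos", "risk_allele", "other_allele")


def read_risk_alleles(path) -> list[RiskAllele]:
    """Read a risk-allele TSV (rsid, chrom, pos, risk_allele, other_allele,
    optional odds_ratio / ancestry / gene).

    Redundant rsIDs are deduplicated (first occurrence kept, drop logged),
    mirroring the redundancy filter applied to GWAS-catalog tables. Rows whose
    risk and other alleles coincide are rejected.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    df.columns = [c.lower() for c in df.columns]
    missing = [c for c in RISK_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"risk table {path} missing column(s): {missing}")
    out: list[RiskAllele] = []
    seen: set[str] = set()
    n_dup = 0
    for _, row in df.iterrows():
        rsid = row["rsid"]
        if rsid in seen:
            n_dup += 1
            continue
        seen.add(rsid)
        orr = row.get("odds_ratio")
        if orr is None or pd.isna(orr) or str(orr) == "":
            odds_ratio = None
            logger.warning("risk allele %s has no odds ratio; retained", rsid)
        else:
            odds_ratio = float(orr)
        if row["risk_allele"] == row["other_allele"]:
            raise ValueError(f"{rsid}: risk allele equals other allele")
        anc = row.get("ancestry")
        gene = row.get("gene")
        out.append(
            RiskAllele(
                rsid=rsid,
                chrom=str(row["chrom"]),
                pos=int(row["pos"]),
                risk_allele=row["risk_allele"],
                other_allele=row["other_allele"],
                odds_ratio=odds_ratio,
                ancestry=None if anc is None or pd.isna(anc) else str(anc),
                gene=None if gene is None or pd.isna(gene) else str(gene),
            )
        )
    if n_dup:
        logger.info("read_risk_alleles(%s): dropped %d redundant rsID(s)", path, n_dup)
    return out


def align_risk_alleles(
    risk: Sequence[RiskAllele], gm: GenotypeMatrix
) -> AlignedRiskMatrix:
    """Match risk alleles to VCF loci and orient dosages to count risk alleles.

    Matching is by (chrom, pos) with an rsID cross-check against the VCF ID
    column (a disagreement is logged, position wins). When the risk allele is
    ALT the dosage is copied; when it is REF the dosage is flipped (2 - d,
    missing stays missing); when it matches neither, or the locus is absent
    from the VCF, the allele is moved to ``dropped`` with a reason. No strand
    flipping is attempted.
    """
    if not risk:
        raise ValueError("empty risk-allele list")
    if gm.n_variants == 0:
        raise ValueError("empty genotype matrix")
    locus_index = {(l.chrom, l.pos): i for i, l in enumerate(gm.loci)}
    kept: list[RiskAllele] = []
    kept_loci: list[Locus] = []
    rows: list[np.ndarray] = []
    flipped: list[bool] = []
    dropped: list[tuple[RiskAllele, str]] = []
    for ra in risk:
        idx = locus_index.get((ra.chrom, ra.pos))
        if idx is None:
            dropped.append((ra, "locus absent from VCF"))
            continue
        locus = gm.loci[idx]
        if locus.id and ra.rsid and locus.id != ra.rsid and not locus.id.startswith(f"{locus.chrom}:"):
            logger.warning(
                "rsID mismatch at %s:%d (table %s, VCF %s); using position",
                ra.chrom, ra.pos, ra.rsid, locus.id,
            )
        d = gm.dosages[idx]
        if ra.risk_allele == locus.alt:
            row, flip = d.copy(), False
        elif ra.risk_allele == locus.ref:
            row = np.where(d == MISSING, MISSING, 2 - d).astype(d.dtype)
            flip = True
        else:
            dropped.append(
                (ra, f"allele mismatch (risk {ra.risk_allele}, VCF {locus.ref}/{locus.alt})")
            )
            continue
        kept.append(ra)
        kept_loci.append(locus)
        rows.append(row)
        flipped.append(flip)
    dosages = (
        np.vstack(rows) if rows else np.empty((0, gm.n_samples), dtype=np.int16)
    )
    return AlignedRiskMatrix(
        risk_alleles=kept,
        dosages=dosages,
        sample_ids=list(gm.sample_ids),
        loci=kept_loci,
        flipped=np.array(flipped, dtype=bool),
        dropped=dropped,
    )


def group_counts(
    dosages: np.ndarray, sample_idx: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """ALT-allele count and chromosome count per variant over a sample subset.

    Missing genotypes are excluded from both numerator and denominator.
    """
    sub = dosages[:, sample_idx]
    obs = sub != MISSING
    alt = np.where(obs, sub, 0).sum(axis=1)
    n_chrom = 2 * obs.sum(axis=1)
    return alt.astype(np.int64), n_chrom.astype(np.int64)


def allele_frequencies(
    gm: GenotypeMatrix,
    panel: SamplePanel,
    level: GroupLevel = "super",
) -> pd.DataFrame:
    """Per-(variant, group) allele counts and frequencies.

    Returns a long-form frequency table with columns ``variant`` (index into
    ``gm.loci``), ``id``, ``group``, ``n_chromosomes``, ``alt_count``,
    ``alt_freq``, ``maf``. ``level='global'`` pools every sample into one
    group. Samples present in the matrix but absent from the panel are an
    error.
    """
    unknown = [s for s in gm.sample_ids if s not in panel.entries]
    if unknown:
        raise ValueError(f"samples absent from panel: {unknown[:10]}")
    frames = []
    for group, samples in sorted(panel.groups(level).items()):
        idx = gm.sample_indices(samples)
        alt, n_chrom = group_counts(gm.dosages, idx)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = np.where(n_chrom > 0, alt / np.maximum(n_chrom, 1), np.nan)
        frames.append(
            pd.DataFrame(
                {
                    "variant": np.arange(gm.n_variants),
                    "id": [l.id for l in gm.loci],
                    "group": group,
                    "n_chromosomes": n_chrom,
                    "alt_count": alt,
                    "alt_freq": freq,
                    "maf": np.minimum(freq, 1 - freq),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def write_frequency_table(freq: pd.DataFrame, path) -> None:
    freq.to_csv(path, sep="\t", index=False, float_format="%.6g")
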