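"""Synthetic genotype/phenotype cohorts with planted, recoverable structure.

The generator emulates the statistical shape of a subtype-stratified GWAS
cohort: four phenotypic case subgroups (paper-scale sizes 639/478/363/387)
plus a shared control group, biallelic SNPs in Hardy-Weinberg equilibrium at
a control minor-allele frequency, and a 123-item severity questionnaire
whose per-subtype mean profiles ("archetypes") drive clustering.

Effects can be planted in two ways:

* case-control effects shift the risk-allele frequency in targeted subtypes
  on the logit scale, so a planted odds ratio OR at control frequency m puts
  case carriers at m' = OR*m/(1-m) / (1 + OR*m/(1-m)) — directly the allelic
  odds ratio the association test estimates;
* quantitative-trait effects add beta * (risk-allele copies) to one trait.

Everything is deterministic given the config seed; per-component random
streams are spawned from it, so genotypes do not change when, e.g., the
item-score noise draw order changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import MISSING_CALL, GenotypeDataset, SampleRecord, VariantRecord

#: paper-scale default cohort: cases per subtype (severe..mild) and controls
DEFAULT_CASES_PER_SUBTYPE = (639, 478, 363, 387)
DEFAULT_N_CONTROLS = 2438

N_ITEMS = 123

#: item-column blocks used by the default archetypes and trait definitions
ITEM_BLOCKS = {
    "language": (0, 20),
    "nonverbal": (20, 40),
    "play": (40, 60),
    "sameness": (60, 80),
    "social": (80, 100),
    "other": (100, 111),
    "savant": (111, 123),
}


def item_names(n_items: int = N_ITEMS) -> list[str]:
    return [f"item{i + 1:03d}" for i in range(n_items)]


def default_archetypes() -> np.ndarray:
    """4 x 123 mean-severity profiles, most to least severe.

    Subtype 0 is severely language-impaired (spoken-language block near the
    ceiling), subtype 1 intermediate, subtype 2 moderate with elevated
    savant-skill items, subtype 3 mild across the board.
    """
    profiles = {
        # block:   (severe, intermediate, moderate, mild)
        "language": (2.7, 1.4, 1.0, 0.4),
        "nonverbal": (2.2, 1.8, 1.2, 0.6),
        "play": (2.2, 1.8, 1.3, 0.6),
        "sameness": (1.8, 1.5, 1.2, 0.5),
        "social": (2.2, 1.8, 1.2, 0.6),
        "other": (1.8, 1.5, 1.0, 0.5),
        "savant": (0.5, 0.3, 1.8, 0.2),
    }
    archetypes = np.zeros((4, N_ITEMS))
    for block, (start, stop) in ITEM_BLOCKS.items():
        for subtype in range(4):
            archetypes[subtype, start:stop] = profiles[block][subtype]
    return archetypes


def synthetic_trait_definitions(n_items: int = N_ITEMS) -> dict[str, list[str]]:
    """Trait -> item-name lists matching the archetype blocks."""
    names = item_names(n_items)
    return {
        trait: names[start:stop]
        for trait, (start, stop) in ITEM_BLOCKS.items()
        if trait in ("language", "nonverbal", "play", "sameness", "social")
    }


@dataclass(frozen=True)
class PlantedCCEffect:
    """Case-control effect: risk-allele odds ratio in a set of subtypes."""

    snp_index: int
    subtypes: frozenset[int]
    odds_ratio: float

    def __post_init__(self) -> None:
        if self.odds_ratio <= 0:
            raise ValueError("odds_ratio must be positive")


@dataclass(frozen=True)
class PlantedQTEffect:
    """Quantitative-trait effect: additive beta per risk-allele copy."""

    snp_index: int
    trait: str
    beta: float


@dataclass
class SimulationConfig:
    n_cases_per_subtype: tuple[int, int, int, int] = DEFAULT_CASES_PER_SUBTYPE
    n_controls: int = DEFAULT_N_CONTROLS
    n_snps: int = 2000
    maf_range: tuple[float, float] = (0.05, 0.5)
    archetypes: np.ndarray = field(default_factory=default_archetypes)
    severity_noise_sd: float = 0.3
    item_missing_rate: float = 0.02
    geno_missing_rate: float = 0.0
    planted_cc_effects: list[PlantedCCEffect] = field(default_factory=list)
    planted_qt_effects: list[PlantedQTEffect] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        self.archetypes = np.asarray(self.archetypes, dtype=float)
        if self.archetypes.shape[0] != len(self.n_cases_per_subtype):
            raise ValueError("archetypes rows must match number of subtypes")
        if not (0 < self.maf_range[0] <= self.maf_range[1] <= 0.5):
            raise ValueError("maf_range must be an interval within (0, 0.5]")
        if not 0 <= self.item_missing_rate < 1:
            raise ValueError("item_missing_rate must be in [0, 1)")
        if self.severity_noise_sd < 0:
            raise ValueError("severity_noise_sd must be nonnegative")
        for eff in self.planted_cc_effects + self.planted_qt_effects:
            if not 0 <= eff.snp_index < self.n_snps:
                raise ValueError(f"planted snp_index {eff.snp_index} out of range")

    @property
    def n_cases(self) -> int:
        return int(sum(self.n_cases_per_subtype))

    @property
    def n_subtypes(self) -> int:
        return len(self.n_cases_per_subtype)


@dataclass
class GroundTruth:
    """What was planted: labels, control MAFs, risk alleles, effects."""

    subtype_labels: pd.Series  # case id -> subtype index
    control_maf: np.ndarray  # per SNP: control frequency of the risk allele
    risk_alleles: list[str]  # per SNP: allele label the planted effects refer to
    cc_effects: list[PlantedCCEffect]
    qt_effects: list[PlantedQTEffect]

    def risk_dosage(self, dataset: GenotypeDataset, snp_index: int) -> np.ndarray:
        """Copies of the risk allele per sample (NaN = missing call).

        The dataset's coded allele may be either the risk allele or its
        partner (coding is canonicalised to PED file-observation order), so
        the dosage is flipped when needed.
        """
        calls = dataset.calls[:, snp_index].astype(float)
        calls[calls == MISSING_CALL] = np.nan
        if dataset.variants[snp_index].allele_b == self.risk_alleles[snp_index]:
            return calls
        return 2.0 - calls


def shifted_frequency(maf: float, odds_ratio: float) -> float:
    """Risk-allele frequency after a logit shift by log(OR)."""
    odds = odds_ratio * maf / (1 - maf)
    return odds / (1 + odds)


def _component_rngs(seed: int, names: Sequence[str]) -> dict[str, np.random.Generator]:
    streams = np.random.SeedSequence(seed).spawn(len(names))
    return {name: np.random.default_rng(s) for name, s in zip(names, streams)}


def simulate_genotypes(config: SimulationConfig) -> tuple[GenotypeDataset, GroundTruth]:
    """Draw a case-control genotype matrix under HWE with planted effects.

    Controls are genotyped per SNP as Binomial(2, m) with m ~ U(maf_range).
    Cases in subtypes targeted by a planted case-control effect use the
    shifted frequency m' (see :func:`shifted_frequency`); all other case
    genotypes use control frequencies.  The ground truth records which
    allele label the planted frequencies refer to (coding may be flipped to
    canonical file order); use :meth:`GroundTruth.risk_dosage` to recover
    risk-allele copies.
    """
    rngs = _component_rngs(config.seed, ["maf", "alleles", "geno", "missing"])
    n_snps = config.n_snps
    maf = rngs["maf"].uniform(config.maf_range[0], config.maf_range[1], size=n_snps)

    bases = np.array(list("ACGT"))
    allele_pairs = [
        rngs["alleles"].choice(bases, size=2, replace=False) for _ in range(n_snps)
    ]
    variants = [
        VariantRecord(
            chrom=str(1 + j % 22),
            snp_id=f"snp{j + 1:05d}",
            bp=1 + 1000 * j,
            allele_a=str(pair[0]),
            allele_b=str(pair[1]),
        )
        for j, pair in enumerate(allele_pairs)
    ]

    subtype_labels = np.repeat(
        np.arange(config.n_subtypes), config.n_cases_per_subtype
    )
    case_ids = [f"case{i + 1:05d}" for i in range(config.n_cases)]
    control_ids = [f"ctrl{i + 1:05d}" for i in range(config.n_controls)]
    samples = [
        SampleRecord(f"F{cid}", cid, "case") for cid in case_ids
    ] + [SampleRecord(f"F{cid}", cid, "control") for cid in control_ids]

    # per-SNP frequency matrix for cases: start at control MAF, shift planted
    case_freq = np.tile(maf, (config.n_subtypes, 1))
    for eff in config.planted_cc_effects:
        m_shift = shifted_frequency(maf[eff.snp_index], eff.odds_ratio)
        for subtype in eff.subtypes:
            case_freq[subtype, eff.snp_index] = m_shift

    geno = rngs["geno"]
    case_calls = geno.binomial(2, case_freq[subtype_labels, :])
    control_calls = geno.binomial(2, np.tile(maf, (config.n_controls, 1)))
    calls = np.vstack([case_calls, control_calls]).astype(np.int8)
    if config.geno_missing_rate > 0:
        drop = rngs["missing"].random(calls.shape) < config.geno_missing_rate
        calls[drop] = MISSING_CALL

    # canonicalise coding to PED observation order: after writing and
    # re-reading, allele_a must be the first allele encountered in the file,
    # so flip any SNP whose first non-missing call is homozygous allele_b
    risk_alleles = [v.allele_b for v in variants]
    for j in range(n_snps):
        col = calls[:, j]
        nonmiss = np.flatnonzero(col != MISSING_CALL)
        if len(nonmiss) and col[nonmiss[0]] == 2:
            v = variants[j]
            variants[j] = VariantRecord(v.chrom, v.snp_id, v.bp, v.allele_b, v.allele_a)
            col[nonmiss] = 2 - col[nonmiss]

    dataset = GenotypeDataset(samples=samples, variants=variants, calls=calls)
    truth = GroundTruth(
        subtype_labels=pd.Series(subtype_labels, index=case_ids),
        control_maf=maf,
        risk_alleles=risk_alleles,
        cc_effects=list(config.planted_cc_effects),
        qt_effects=list(config.planted_qt_effects),
    )
    return dataset, truth


def simulate_item_scores(
    config: SimulationConfig, subtype_labels: pd.Series
) -> pd.DataFrame:
    """Raw item codes per case: rounded, clamped noisy archetype profiles.

    score = clamp(round(archetype[subtype, item] + N(0, severity_noise_sd)),
    0, 3); with probability ``item_missing_rate`` the cell instead carries a
    not-applicable/not-asked raw code (8 or 9), which the default recode map
    treats as missing.
    """
    rngs = _component_rngs(config.seed, ["items", "item_missing"])
    labels = subtype_labels.to_numpy()
    n_cases = len(labels)
    n_items = config.archetypes.shape[1]
    means = config.archetypes[labels, :]
    noisy = means + rngs["items"].normal(0.0, config.severity_noise_sd, size=means.shape)
    scores = np.clip(np.rint(noisy), 0, 3).astype(int)
    if config.item_missing_rate > 0:
        miss_rng = rngs["item_missing"]
        mask = miss_rng.random(scores.shape) < config.item_missing_rate
        codes = miss_rng.choice([8, 9], size=scores.shape)
        scores = np.where(mask, codes, scores)
    return pd.DataFrame(
        scores, index=subtype_labels.index, columns=item_names(n_items)
    )


def plant_qt_effect(
    dataset: GenotypeDataset,
    trait_table: pd.DataFrame,
    effects: Sequence[PlantedQTEffect],
    ground_truth: GroundTruth | None = None,
) -> pd.DataFrame:
    """Add beta * (risk-allele copies) to targeted traits; returns a copy.

    ``trait_table`` rows are matched to case individual ids.  A missing
    genotype contributes no dosage.  When ``ground_truth`` is given the
    dosage counts the recorded risk allele; otherwise it counts the coded
    ``allele_b``.  Traits not named by any effect are returned unchanged.
    """
    table = trait_table.copy()
    if not effects:
        return table
    case_ids = pd.Index(dataset.case_ids())
    case_rows = dataset.case_indices
    for eff in effects:
        if eff.trait not in table.columns:
            raise KeyError(f"trait {eff.trait!r} not in trait table")
        if ground_truth is not None:
            dosage = ground_truth.risk_dosage(dataset, eff.snp_index)[case_rows]
            dosage = np.nan_to_num(dosage, nan=0.0)
        else:
            dosage = dataset.calls[case_rows, eff.snp_index].astype(float)
            dosage[dosage == MISSING_CALL] = 0.0
        dose = pd.Series(dosage, index=case_ids).reindex(table.index).fillna(0.0)
        table[eff.trait] = table[eff.trait] + eff.beta * dose
    return table
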