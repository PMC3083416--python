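"""Calibration and parameter-recovery experiments on the synthetic generator.

These routines exercise the whole stack under known ground truth: type-I
error of the allelic test on null SNPs, detection of a subtype-specific
planted odds ratio, power of the quantitative-trait screen for a planted
additive effect, and recovery of planted phenotypic subtypes by
clustering.  They are used by the test suite and the reproduction script;
each is deterministic given its seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from . import phenotype_traits, subtyping
from .association import assoc_test
from .pipeline import qt_screen, subtype_assoc
from .synthetic_data import (
    DEFAULT_CASES_PER_SUBTYPE,
    DEFAULT_N_CONTROLS,
    PlantedCCEffect,
    PlantedQTEffect,
    SimulationConfig,
    plant_qt_effect,
    simulate_genotypes,
    simulate_item_scores,
    synthetic_trait_definitions,
)

_SUBTYPE_NAMES = list(subtyping.K4_NAMES)


def _spawn_seeds(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def allelic_type_i_error(
    n_snps: int = 5000,
    n_cases: int = 500,
    n_controls: int = 500,
    maf: float = 0.3,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Empirical rejection rate of the allelic test on null SNPs."""
    per_subtype = n_cases // 4
    config = SimulationConfig(
        n_cases_per_subtype=(per_subtype,) * 4,
        n_controls=n_controls,
        n_snps=n_snps,
        maf_range=(maf, maf),
        seed=seed,
    )
    dataset, _ = simulate_genotypes(config)
    cases = dataset.case_indices
    controls = dataset.control_indices
    rejections = sum(
        assoc_test(dataset, cases, controls, j).p_unadj < alpha
        for j in range(n_snps)
    )
    return rejections / n_snps


def subtype_detection_rate(
    n_seeds: int = 50,
    odds_ratio: float = 2.0,
    target_subtype: int = 0,
    off_subtype: int = 2,
    qtl_set_size: int = 20,
    maf: float = 0.3,
    bonf_threshold: float = 0.05,
    seed: int = 0,
) -> dict[str, float]:
    """Detection of a planted subtype-specific effect at paper-scale n.

    Per seed, one SNP of a ``qtl_set_size``-SNP set carries odds ratio
    ``odds_ratio`` in the target subtype only (cohort 639/478/363/387 cases
    vs 2438 controls).  Reports the fraction of seeds where the planted SNP
    is Bonferroni-significant in the target subtype, where it stays
    non-significant in the untargeted subtype, and where both hold.
    """
    hit_target = hit_clean = hit_both = 0
    for s in _spawn_seeds(seed, n_seeds):
        config = SimulationConfig(
            n_cases_per_subtype=DEFAULT_CASES_PER_SUBTYPE,
            n_controls=DEFAULT_N_CONTROLS,
            n_snps=qtl_set_size,
            maf_range=(maf, maf),
            planted_cc_effects=[
                PlantedCCEffect(0, frozenset({target_subtype}), odds_ratio)
            ],
            seed=s,
        )
        dataset, truth = simulate_genotypes(config)
        labels = truth.subtype_labels.map(dict(enumerate(_SUBTYPE_NAMES)))
        tables = subtype_assoc(
            dataset, {"trait": dataset.snp_ids}, labels
        )
        frame = tables["trait"]
        planted = frame[frame["SNP"] == dataset.variants[0].snp_id].set_index(
            "SUBTYPE"
        )
        in_target = planted.loc[_SUBTYPE_NAMES[target_subtype], "BONF"] <= bonf_threshold
        off_clean = planted.loc[_SUBTYPE_NAMES[off_subtype], "BONF"] > bonf_threshold
        hit_target += in_target
        hit_clean += off_clean
        hit_both += in_target and off_clean
    return {
        "target_significant": hit_target / n_seeds,
        "off_subtype_clean": hit_clean / n_seeds,
        "both": hit_both / n_seeds,
    }


def qt_screen_power(
    n_seeds: int = 100,
    beta: float = 3.0,
    n_cases: int = 1500,
    maf: float = 0.3,
    n_snps: int = 20,
    trait: str = "sameness",
    threshold: float = 1e-5,
    seed: int = 0,
) -> float:
    """Fraction of seeds in which a planted QT effect passes the screen.

    Per seed a cohort of ``n_cases`` cases (split 500/400/300/300 at the
    default) is simulated, the planted SNP adds ``beta`` per risk-allele
    copy to one behavioural trait, and the screen keeps SNPs with
    regression p <= threshold.
    """
    sizes = (
        n_cases // 3,
        n_cases - n_cases // 3 - 2 * (n_cases // 5),
        n_cases // 5,
        n_cases // 5,
    )
    hits = 0
    for s in _spawn_seeds(seed, n_seeds):
        config = SimulationConfig(
            n_cases_per_subtype=sizes,
            n_controls=10,
            n_snps=n_snps,
            maf_range=(maf, maf),
            seed=s,
        )
        dataset, truth = simulate_genotypes(config)
        items = simulate_item_scores(config, truth.subtype_labels)
        severities = phenotype_traits.recode_items(items)
        table = phenotype_traits.trait_sums(
            severities, synthetic_trait_definitions()
        )[[trait]]
        table = plant_qt_effect(
            dataset, table, [PlantedQTEffect(0, trait, beta)], truth
        )
        qtl = qt_screen(dataset, table, threshold)
        hits += dataset.variants[0].snp_id in qtl[trait]
    return hits / n_seeds


def clustering_recovery(
    sizes: tuple[int, ...] = DEFAULT_CASES_PER_SUBTYPE,
    severity_noise_sd: float = 0.3,
    item_missing_rate: float = 0.02,
    n_restarts: int = 10,
    seed: int = 0,
) -> dict[str, object]:
    """Recovery of planted phenotypic subtypes by K-means at paper scale.

    Returns the adjusted Rand index between planted and recovered labels
    and whether the recovered cluster sizes match the planted sizes exactly.
    """
    config = SimulationConfig(
        n_cases_per_subtype=sizes,
        n_controls=1,
        n_snps=1,
        severity_noise_sd=severity_noise_sd,
        item_missing_rate=item_missing_rate,
        seed=seed,
    )
    _, truth = simulate_genotypes(config)
    items = simulate_item_scores(config, truth.subtype_labels)
    severities = phenotype_traits.recode_items(items)
    assignment = subtyping.kmeans_cluster(
        severities, k=len(sizes), n_restarts=n_restarts, seed=seed
    )
    rand = adjusted_rand_score(
        truth.subtype_labels.to_numpy(), assignment.labels.to_numpy()
    )
    recovered = sorted(assignment.cluster_sizes().values())
    return {
        "rand_index": float(rand),
        "sizes_match": recovered == sorted(sizes),
        "recovered_sizes": recovered,
        "n_cases": int(sum(sizes)),
    }
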