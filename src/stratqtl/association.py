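"""Core association statistics and SNP quality control.

Implements the allelic case-control test (1-df Pearson chi-square on the
2x2 minor/major x case/control allele table, no continuity correction), the
minor-allele odds ratio, per-SNP quantitative-trait linear regression with
additive genotype coding, the Hardy-Weinberg equilibrium goodness-of-fit
test, and the standard missingness/MAF/HWE variant filters.

Conventions
-----------
* The minor allele A1 is the allele with the lower combined (cases+controls)
  frequency at that SNP; ties break lexicographically on the allele label.
* The odds ratio is oriented to A1: OR = odds of the minor allele in cases
  over the same odds in controls, so OR > 1 means the minor allele is
  enriched in cases.
* Missing genotypes are dropped per SNP (complete-case); allele frequencies
  use non-missing calls only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io_formats import MISSING_CALL, GenotypeDataset, VariantRecord


@dataclass(frozen=True)
class AlleleCounts2x2:
    """Allele counts (2 per genotyped individual) in the case/control x minor/major table."""

    case_minor: int
    case_major: int
    control_minor: int
    control_major: int

    def __post_init__(self) -> None:
        for name in ("case_minor", "case_major", "control_minor", "control_major"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


@dataclass
class AssocRow:
    """Allelic-test result for one SNP: frequencies, chi-square, OR, p."""

    variant: VariantRecord
    a1: str
    a2: str
    f_a: float
    f_u: float
    chisq: float
    or_a1: float  # NaN when a zero cell makes the OR undefined
    p_unadj: float
    n_case_used: int
    n_control_used: int


@dataclass
class QTAssocRow:
    """Per-SNP linear-regression result: trait ~ additive allele dosage."""

    variant: VariantRecord | None
    beta: float
    se: float
    stat: float
    p_unadj: float
    n_used: int
    testable: bool = True


def chisq_p(chisq: float, df: int = 1) -> float:
    """Upper-tail probability of a chi-square statistic."""
    if chisq < 0:
        raise ValueError("chisq must be nonnegative")
    if df < 1:
        raise ValueError("df must be a positive integer")
    return float(stats.chi2.sf(chisq, df))


def minor_allele_and_counts(
    dataset: GenotypeDataset,
    case_indices: np.ndarray,
    control_indices: np.ndarray,
    variant_index: int,
) -> tuple[str, str, AlleleCounts2x2]:
    """Orient a SNP to its minor allele and tally the 2x2 allele table.

    Individuals with a missing call at this SNP are excluded.  The minor
    allele is the one with lower combined frequency across cases and
    controls; an exact tie breaks lexicographically on the allele label.

    Raises
    ------
    ValueError
        If every case and control call is missing at this SNP.
    """
    variant = dataset.variants[variant_index]
    col = dataset.calls[:, variant_index]

    def _tally(indices: np.ndarray) -> tuple[int, int]:
        sub = col[np.asarray(indices, dtype=int)] if len(indices) else np.array([], dtype=np.int8)
        sub = sub[sub != MISSING_CALL]
        b = int(sub.sum())
        total = 2 * len(sub)
        return b, total - b

    case_b, case_a = _tally(case_indices)
    ctrl_b, ctrl_a = _tally(control_indices)
    total = case_b + case_a + ctrl_b + ctrl_a
    if total == 0:
        raise ValueError(f"variant {variant.snp_id}: all calls missing")

    freq_b = (case_b + ctrl_b) / total
    if freq_b < 0.5:
        minor, major = variant.allele_b, variant.allele_a
        counts = AlleleCounts2x2(case_b, case_a, ctrl_b, ctrl_a)
    elif freq_b > 0.5:
        minor, major = variant.allele_a, variant.allele_b
        counts = AlleleCounts2x2(case_a, case_b, ctrl_a, ctrl_b)
    else:  # tie: lexicographic on the allele label
        if variant.allele_a <= variant.allele_b:
            minor, major = variant.allele_a, variant.allele_b
            counts = AlleleCounts2x2(case_a, case_b, ctrl_a, ctrl_b)
        else:
            minor, major = variant.allele_b, variant.allele_a
            counts = AlleleCounts2x2(case_b, case_a, ctrl_b, ctrl_a)
    return minor, major, counts


def allelic_chisq(counts: AlleleCounts2x2, haldane: bool = False) -> dict:
    """1-df Pearson allelic test on a 2x2 allele table, with minor-allele OR.

    chisq = N(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d)) with a = case minor,
    b = case major, c = control minor, d = control major; no continuity
    correction.  OR = ad/bc, oriented to the minor allele.  With a zero
    cell the OR is NaN unless ``haldane`` adds 0.5 to every cell
    (Haldane-Anscombe) for the OR only.

    Raises
    ------
    ValueError
        If a table margin (all case alleles, all control alleles, all minor,
        or all major) is zero, leaving the statistic undefined.
    """
    a, b = counts.case_minor, counts.case_major
    c, d = counts.control_minor, counts.control_major
    n_case, n_ctrl = a + b, c + d
    n_minor, n_major = a + c, b + d
    if min(n_case, n_ctrl, n_minor, n_major) == 0:
        raise ValueError("zero margin in 2x2 allele table; statistic undefined")

    n = a + b + c + d
    chisq = n * (a * d - b * c) ** 2 / (n_case * n_ctrl * n_minor * n_major)
    if min(a, b, c, d) == 0:
        or_a1 = (
            ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5)) if haldane else np.nan
        )
    else:
        or_a1 = (a * d) / (b * c)
    return {
        "f_a": a / n_case,
        "f_u": c / n_ctrl,
        "chisq": float(chisq),
        "or_a1": float(or_a1),
        "p_unadj": chisq_p(float(chisq), 1),
    }


def assoc_test(
    dataset: GenotypeDataset,
    case_indices: np.ndarray,
    control_indices: np.ndarray,
    variant_index: int,
    haldane: bool = False,
) -> AssocRow:
    """Full allelic association of one SNP: orientation, counts, test."""
    a1, a2, counts = minor_allele_and_counts(
        dataset, case_indices, control_indices, variant_index
    )
    res = allelic_chisq(counts, haldane=haldane)
    return AssocRow(
        variant=dataset.variants[variant_index],
        a1=a1,
        a2=a2,
        n_case_used=(counts.case_minor + counts.case_major) // 2,
        n_control_used=(counts.control_minor + counts.control_major) // 2,
        **res,
    )


def qt_linear_assoc(genotypes: np.ndarray, traits: np.ndarray) -> QTAssocRow:
    """Simple linear regression of a quantitative trait on allele dosage.

    ``genotypes`` are 0/1/2 copies of A1 (NaN or MISSING_CALL = missing);
    ``traits`` are trait values (NaN = missing).  Pairs with either value
    missing are dropped.  p is two-sided from t with n-2 df.  A SNP with
    fewer than 3 usable pairs or zero genotype variance is flagged
    untestable; a constant trait gives beta = 0, p = 1.
    """
    g = np.asarray(genotypes, dtype=float).copy()
    g[g == MISSING_CALL] = np.nan
    y = np.asarray(traits, dtype=float)
    keep = ~(np.isnan(g) | np.isnan(y))
    g, y = g[keep], y[keep]
    n = len(g)
    if n < 3 or np.var(g) == 0:
        return QTAssocRow(None, np.nan, np.nan, np.nan, np.nan, n, testable=False)
    if np.var(y) == 0:
        return QTAssocRow(None, 0.0, 0.0, 0.0, 1.0, n)
    fit = stats.linregress(g, y)
    return QTAssocRow(
        variant=None,
        beta=float(fit.slope),
        se=float(fit.stderr),
        stat=float(fit.slope / fit.stderr) if fit.stderr > 0 else np.inf,
        p_unadj=float(fit.pvalue),
        n_used=n,
    )


def hwe_test(hom_a: int, het: int, hom_b: int) -> float:
    """Hardy-Weinberg goodness-of-fit p-value (1-df Pearson chi-square).

    Observed genotype counts are compared with p^2 : 2pq : q^2 expectations
    at the sample allele frequency.  A monomorphic sample is in perfect
    equilibrium (p = 1).
    """
    n = hom_a + het + hom_b
    if n <= 0:
        raise ValueError("total genotype count must be positive")
    p = (2 * hom_a + het) / (2 * n)
    q = 1 - p
    if p == 0 or q == 0:
        return 1.0
    expected = np.array([n * p * p, 2 * n * p * q, n * q * q])
    observed = np.array([hom_a, het, hom_b], dtype=float)
    chisq = float(((observed - expected) ** 2 / expected).sum())
    return chisq_p(chisq, 1)


def qc_filter(
    dataset: GenotypeDataset,
    max_missing: float = 0.10,
    min_maf: float = 0.01,
    hwe_alpha: float = 0.001,
) -> tuple[GenotypeDataset, dict[str, list[str]]]:
    """Drop variants failing missingness, MAF, or control-HWE rules.

    Rules (a variant failing any is removed; the report lists all reasons):

    * ``missingness`` — missing in more than ``max_missing`` of all samples;
    * ``maf`` — minor allele frequency (non-missing calls, cases+controls)
      below ``min_maf``;
    * ``hwe`` — Hardy-Weinberg p below ``hwe_alpha`` in controls only.
    """
    for name, value in (("max_missing", max_missing), ("min_maf", min_maf), ("hwe_alpha", hwe_alpha)):
        if not 0 < value < 1:
            raise ValueError(f"{name} must be in (0, 1)")

    calls = dataset.calls
    controls = dataset.control_indices
    report: dict[str, list[str]] = {}
    keep: list[int] = []
    for j, variant in enumerate(dataset.variants):
        col = calls[:, j]
        reasons = []
        missing_frac = np.mean(col == MISSING_CALL)
        if missing_frac > max_missing:
            reasons.append("missingness")
        nonmiss = col[col != MISSING_CALL]
        if len(nonmiss) == 0:
            if "missingness" not in reasons:
                reasons.append("missingness")
        else:
            f_b = nonmiss.sum() / (2 * len(nonmiss))
            if min(f_b, 1 - f_b) < min_maf:
                reasons.append("maf")
        ctrl = col[controls] if len(controls) else np.array([], dtype=np.int8)
        ctrl = ctrl[ctrl != MISSING_CALL]
        if len(ctrl) > 0:
            counts = [int((ctrl == g).sum()) for g in (0, 1, 2)]
            if hwe_test(*counts) < hwe_alpha:
                reasons.append("hwe")
        if reasons:
            report[variant.snp_id] = reasons
        else:
            keep.append(j)
    return dataset.subset_variants(keep), report
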