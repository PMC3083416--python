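"""Three-stage subtype-stratified association design and replication report.

Stage 1 (discovery): per-trait quantitative-trait regression over all
post-QC SNPs in genotyped cases screens SNPs at an unadjusted p <= 1e-5,
yielding one QTL set per trait.

Stage 2: each trait's QTL set is tested for allelic case-control
association with cases split into K phenotypic subtypes (each subtype vs
all controls) and as a combined group.  Bonferroni and Benjamini-Hochberg
adjustments use m = |trait QTL set| within each (trait x group) run.

Stage 3: SNPs Bonferroni-significant (p <= 0.05) in at least one subtype
are pooled into a combined list and re-tested per subtype and combined,
with m = |combined list|.  Combined-case rows are always reported but never
drive selection.  The replication report groups final SNPs by the set of
subtypes in which they are significant (Bonferroni) or suggestive (BH FDR),
exposing subtype-dependent odds ratios for shared SNPs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import association, multiple_testing
from .io_formats import GenotypeDataset, write_assoc_table

COMBINED = "Combined"


@dataclass
class PipelineConfig:
    qt_p_threshold: float = 1e-5
    bonf_select_threshold: float = 0.05
    suggestive_fdr_threshold: float = 0.09
    k: int = 4
    trait_definitions: Mapping[str, Sequence[str]] | None = None
    max_missing: float = 0.10
    min_maf: float = 0.01
    hwe_alpha: float = 0.001
    max_missing_trait_fraction: float = 0.2
    n_restarts: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("qt_p_threshold", "bonf_select_threshold", "suggestive_fdr_threshold"):
            value = getattr(self, name)
            if not 0 < value <= 1:
                raise ValueError(f"{name} must be in (0, 1]")


def qt_screen(
    dataset: GenotypeDataset,
    trait_table: pd.DataFrame,
    threshold: float = 1e-5,
) -> dict[str, list[str]]:
    """Per-trait QTL sets: SNPs with regression p <= threshold (inclusive).

    For each trait, every SNP is regressed on additive allele dosage over
    genotyped cases with a non-missing trait value; untestable SNPs
    (monomorphic or too few usable pairs) are never selected.
    """
    case_rows = dataset.case_indices
    case_ids = pd.Index(dataset.case_ids())
    qtl: dict[str, list[str]] = {}
    for trait in trait_table.columns:
        y = trait_table[trait].reindex(case_ids).to_numpy(dtype=float)
        hits = []
        for j, variant in enumerate(dataset.variants):
            g = dataset.calls[case_rows, j].astype(float)
            row = association.qt_linear_assoc(g, y)
            if row.testable and row.p_unadj <= threshold:
                hits.append(variant.snp_id)
        qtl[trait] = hits
    return qtl


def _assoc_frame(
    dataset: GenotypeDataset,
    snp_ids: Sequence[str],
    group_rows: np.ndarray,
    control_rows: np.ndarray,
    group_name: str,
    m_tests: int,
) -> pd.DataFrame:
    """Allelic tests of ``snp_ids`` for one case group, with adjustments."""
    records = []
    for snp_id in snp_ids:
        j = dataset.variant_index(snp_id)
        row = association.assoc_test(dataset, group_rows, control_rows, j)
        records.append(
            {
                "CHR": row.variant.chrom,
                "SNP": snp_id,
                "BP": row.variant.bp,
                "A1": row.a1,
                "F_A": row.f_a,
                "F_U": row.f_u,
                "A2": row.a2,
                "CHISQ": row.chisq,
                "OR": row.or_a1,
                "SUBTYPE": group_name,
                "N_CASES": row.n_case_used,
                "UNADJ": row.p_unadj,
            }
        )
    frame = pd.DataFrame.from_records(records)
    if len(frame):
        frame["FDR_BH"] = multiple_testing.bh_adjust(frame["UNADJ"], m_tests)
        frame["BONF"] = multiple_testing.bonferroni(frame["UNADJ"], m_tests)
    else:
        frame = pd.DataFrame(
            columns=[
                "CHR", "SNP", "BP", "A1", "F_A", "F_U", "A2", "CHISQ", "OR",
                "SUBTYPE", "N_CASES", "UNADJ", "FDR_BH", "BONF",
            ]
        )
    return frame


def _group_rows(
    dataset: GenotypeDataset, subtype_labels: pd.Series
) -> dict[str, np.ndarray]:
    """Sample-row indices per subtype name, plus the combined case group."""
    id_to_row = {
        s.individual_id: i
        for i, s in enumerate(dataset.samples)
        if s.status == "case"
    }
    missing = [cid for cid in subtype_labels.index if cid not in id_to_row]
    if missing:
        raise ValueError(
            f"subtype assignment covers non-genotyped cases, e.g. {missing[0]!r}"
        )
    groups: dict[str, np.ndarray] = {}
    for name in subtype_labels.unique():
        ids = subtype_labels.index[subtype_labels == name]
        groups[str(name)] = np.array([id_to_row[c] for c in ids])
    groups[COMBINED] = np.array(sorted(id_to_row[c] for c in subtype_labels.index))
    return groups


def subtype_assoc(
    dataset: GenotypeDataset,
    qtl_sets: Mapping[str, Sequence[str]],
    subtype_labels: pd.Series,
) -> dict[str, pd.DataFrame]:
    """Stage-2 tables: per trait, allelic tests per subtype and combined.

    ``subtype_labels`` maps case individual id -> subtype name.  Adjustments
    are computed within each (trait x group) run with m = |trait QTL set|;
    runs are never pooled across subtypes.
    """
    control_rows = dataset.control_indices
    groups = _group_rows(dataset, subtype_labels)
    tables: dict[str, pd.DataFrame] = {}
    for trait, snp_ids in qtl_sets.items():
        m = len(snp_ids)
        frames = [
            _assoc_frame(dataset, snp_ids, rows, control_rows, name, m)
            for name, rows in groups.items()
        ]
        tables[trait] = pd.concat(frames, ignore_index=True)
    return tables


def select_and_combine(
    tables: Mapping[str, pd.DataFrame], threshold: float = 0.05
) -> list[str]:
    """Unique SNPs Bonferroni-significant in >= 1 subtype (combined rows excluded)."""
    selected: set[str] = set()
    for frame in tables.values():
        if not len(frame):
            continue
        hits = frame[(frame["SUBTYPE"] != COMBINED) & (frame["BONF"] <= threshold)]
        selected.update(hits["SNP"])
    return sorted(selected)


def final_assoc(
    dataset: GenotypeDataset,
    combined_snps: Sequence[str],
    subtype_labels: pd.Series,
) -> pd.DataFrame:
    """Stage-3 table: the combined SNP list re-tested per subtype and combined.

    Both adjustments use m = len(combined_snps) within each group run.
    """
    if not combined_snps:
        raise ValueError("combined SNP list is empty")
    control_rows = dataset.control_indices
    groups = _group_rows(dataset, subtype_labels)
    m = len(combined_snps)
    frames = [
        _assoc_frame(dataset, combined_snps, rows, control_rows, name, m)
        for name, rows in groups.items()
    ]
    return pd.concat(frames, ignore_index=True)


def replication_report(
    final_table: pd.DataFrame,
    significance_threshold: float = 0.05,
    suggestive_threshold: float = 0.09,
) -> pd.DataFrame:
    """Group final SNPs by the subtypes in which they replicate.

    A SNP "appears" in a subtype when its Bonferroni p <= the significance
    threshold or its BH FDR p < the suggestive threshold there; combined-case
    rows are ignored.  Returns one row per appearing SNP with the subtype
    set, per-subtype odds ratios, and per-subtype adjusted p-values, sorted
    by the number of sharing subtypes (descending).
    """
    rows = final_table[final_table["SUBTYPE"] != COMBINED]
    appears = rows[
        (rows["BONF"] <= significance_threshold)
        | (rows["FDR_BH"] < suggestive_threshold)
    ]
    records = []
    for snp, grp in appears.groupby("SNP"):
        subtypes = list(grp["SUBTYPE"])
        records.append(
            {
                "SNP": snp,
                "N_SUBTYPES": len(subtypes),
                "SUBTYPES": ";".join(subtypes),
                "ORS": ";".join(f"{v:.2f}" for v in grp["OR"]),
                "BONF_PS": ";".join(f"{v:.4f}" for v in grp["BONF"]),
                "FDR_PS": ";".join(f"{v:.4f}" for v in grp["FDR_BH"]),
            }
        )
    report = pd.DataFrame.from_records(
        records,
        columns=["SNP", "N_SUBTYPES", "SUBTYPES", "ORS", "BONF_PS", "FDR_PS"],
    )
    if len(report):
        report = report.sort_values(
            ["N_SUBTYPES", "SNP"], ascending=[False, True]
        ).reset_index(drop=True)
    return report


def annotate(frame: pd.DataFrame, annotation: pd.DataFrame | None) -> pd.DataFrame:
    """Left-join annotation columns (band/gene/location) on SNP id; absent -> blank."""
    if annotation is None:
        return frame
    ann = annotation.copy()
    if "SNP" not in ann.columns:
        raise ValueError("annotation table must have a SNP column")
    merged = frame.merge(ann, on="SNP", how="left")
    extra = [c for c in ann.columns if c != "SNP"]
    merged[extra] = merged[extra].fillna("")
    return merged


@dataclass
class PipelineResult:
    qtl_sets: dict[str, list[str]]
    subtype_tables: dict[str, pd.DataFrame]
    combined_snps: list[str]
    final_table: pd.DataFrame
    replication: pd.DataFrame
    subtype_sizes: dict[str, int] = field(default_factory=dict)


def run_stages(
    dataset: GenotypeDataset,
    trait_table: pd.DataFrame,
    subtype_labels: pd.Series,
    config: PipelineConfig | None = None,
    annotation: pd.DataFrame | None = None,
) -> PipelineResult:
    """Run stages 1-3 plus the replication report on a post-QC dataset."""
    config = config or PipelineConfig()
    qtl_sets = qt_screen(dataset, trait_table, config.qt_p_threshold)
    tables = subtype_assoc(dataset, qtl_sets, subtype_labels)
    combined = select_and_combine(tables, config.bonf_select_threshold)
    if combined:
        final = final_assoc(dataset, combined, subtype_labels)
        final = annotate(final, annotation)
        replication = replication_report(
            final,
            config.bonf_select_threshold,
            config.suggestive_fdr_threshold,
        )
    else:
        final = pd.DataFrame(
            columns=["CHR", "SNP", "BP", "A1", "F_A", "F_U", "A2", "CHISQ",
                     "OR", "SUBTYPE", "N_CASES", "UNADJ", "FDR_BH", "BONF"]
        )
        replication = replication_report(final)
    sizes = subtype_labels.value_counts().to_dict()
    return PipelineResult(
        qtl_sets=qtl_sets,
        subtype_tables=tables,
        combined_snps=combined,
        final_table=final,
        replication=replication,
        subtype_sizes={str(k): int(v) for k, v in sizes.items()},
    )


def write_outputs(result: PipelineResult, outdir: str | Path) -> None:
    """Write per-stage TSVs (qtl_sets, per-trait tables, final, replication)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "qtl_sets.tsv", "w") as fh:
        fh.write("trait\tsnp_id\n")
        for trait, snps in result.qtl_sets.items():
            for snp in snps:
                fh.write(f"{trait}\t{snp}\n")
    for trait, frame in result.subtype_tables.items():
        write_assoc_table(frame, outdir / f"assoc_{trait}.tsv")
    write_assoc_table(result.final_table, outdir / "final_assoc.tsv")
    result.replication.to_csv(outdir / "replication.tsv", sep="\t", index=False)
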