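"""Text I/O for genotypes (PLINK PED/MAP), item-score tables, and association tables.

Genotype calls are stored as copies of ``allele_b`` per variant, where
``allele_b`` is the *second* allele symbol observed in file order when the
PED is first parsed.  Minor-allele orientation is a statistical decision and
is deferred to :mod:`stratqtl.association`; I/O stays deterministic and
orientation-free.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: sentinel for a missing genotype call in the calls matrix
MISSING_CALL = -1

#: placeholder allele label for a variant with fewer than two observed alleles
UNOBSERVED_ALLELE = "."

CASE = "case"
CONTROL = "control"


@dataclass(frozen=True)
class VariantRecord:
    """A biallelic variant: chromosome, identifier, 1-based position, alleles."""

    chrom: str
    snp_id: str
    bp: int
    allele_a: str
    allele_b: str

    def __post_init__(self) -> None:
        if self.bp < 1:
            raise ValueError(f"variant {self.snp_id}: bp must be >= 1, got {self.bp}")
        if self.allele_a == self.allele_b:
            raise ValueError(
                f"variant {self.snp_id}: allele_a and allele_b must differ "
                f"(both {self.allele_a!r})"
            )


@dataclass(frozen=True)
class SampleRecord:
    family_id: str
    individual_id: str
    status: str  # "case" or "control"

    def __post_init__(self) -> None:
        if self.status not in (CASE, CONTROL):
            raise ValueError(f"status must be 'case' or 'control', got {self.status!r}")


@dataclass
class GenotypeDataset:
    """Samples x variants genotype matrix with per-call allele_b dosage 0/1/2.

    ``calls[i, j]`` counts copies of ``variants[j].allele_b`` carried by
    ``samples[i]``; :data:`MISSING_CALL` marks a missing call.
    """

    samples: list[SampleRecord]
    variants: list[VariantRecord]
    calls: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        valid = (self.calls == MISSING_CALL) | (
            (self.calls >= 0) & (self.calls <= 2)
        )
        if not valid.all():
            raise ValueError("calls must be in {0,1,2} or MISSING_CALL")
        ids = [v.snp_id for v in self.variants]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate snp_id in dataset")
        keys = [(s.family_id, s.individual_id) for s in self.samples]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (family_id, individual_id) in dataset")

    # -- convenience accessors -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def snp_ids(self) -> list[str]:
        return [v.snp_id for v in self.variants]

    @property
    def case_indices(self) -> np.ndarray:
        return np.array([i for i, s in enumerate(self.samples) if s.status == CASE])

    @property
    def control_indices(self) -> np.ndarray:
        return np.array([i for i, s in enumerate(self.samples) if s.status == CONTROL])

    def case_ids(self) -> list[str]:
        return [s.individual_id for s in self.samples if s.status == CASE]

    def variant_index(self, snp_id: str) -> int:
        try:
            return self.snp_ids.index(snp_id)
        except ValueError:
            raise KeyError(f"snp_id {snp_id!r} not in dataset") from None

    def subset_variants(self, indices: Sequence[int]) -> "GenotypeDataset":
        idx = list(indices)
        return GenotypeDataset(
            samples=list(self.samples),
            variants=[self.variants[j] for j in idx],
            calls=self.calls[:, idx].copy(),
        )


def read_map(map_path: str | Path) -> list[tuple[str, str, int]]:
    """Parse a MAP file into (chrom, snp_id, bp) tuples (genetic distance ignored)."""
    entries: list[tuple[str, str, int]] = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != 4:
                raise ValueError(
                    f"{map_path}: line {lineno}: expected 4 fields, got {len(fields)}"
                )
            chrom, snp_id, _cm, bp_s = fields
            try:
                bp = int(bp_s)
            except ValueError:
                raise ValueError(
                    f"{map_path}: line {lineno}: non-integer bp {bp_s!r}"
                ) from None
            entries.append((chrom, snp_id, bp))
    if not entries:
        raise ValueError(f"{map_path}: empty MAP file")
    return entries


def read_ped_map(ped_path: str | Path, map_path: str | Path) -> GenotypeDataset:
    """Read PLINK text PED/MAP into a :class:`GenotypeDataset`.

    PED phenotype column: 1 = control, 2 = case; any other value drops the
    sample with a warning.  A call is missing iff either allele token is "0".
    A variant with more than two observed allele symbols is rejected.
    """
    map_entries = read_map(map_path)
    n_var = len(map_entries)

    samples: list[SampleRecord] = []
    rows: list[list[str]] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != 6 + 2 * n_var:
                raise ValueError(
                    f"{ped_path}: line {lineno}: expected {6 + 2 * n_var} fields "
                    f"(6 + 2x{n_var}), got {len(fields)}"
                )
            fid, iid, _pat, _mat, _sex, pheno = fields[:6]
            if pheno == "1":
                status = CONTROL
            elif pheno == "2":
                status = CASE
            else:
                warnings.warn(
                    f"{ped_path}: line {lineno}: sample {fid}/{iid} has "
                    f"phenotype {pheno!r} (not 1/2); excluded",
                    stacklevel=2,
                )
                continue
            samples.append(SampleRecord(fid, iid, status))
            rows.append(fields[6:])

    tokens = np.array(rows, dtype=object).reshape(len(samples), 2 * n_var) if samples else np.empty((0, 2 * n_var), dtype=object)

    variants: list[VariantRecord] = []
    calls = np.full((len(samples), n_var), MISSING_CALL, dtype=np.int8)
    for j, (chrom, snp_id, bp) in enumerate(map_entries):
        t1 = tokens[:, 2 * j]
        t2 = tokens[:, 2 * j + 1]
        observed: list[str] = []
        for tok in np.concatenate([t1, t2]) if len(samples) else []:
            if tok != "0" and tok not in observed:
                observed.append(tok)
        if len(observed) > 2:
            raise ValueError(
                f"variant {snp_id}: more than two alleles observed: {sorted(observed)}"
            )
        allele_a = observed[0] if observed else UNOBSERVED_ALLELE
        allele_b = observed[1] if len(observed) > 1 else UNOBSERVED_ALLELE
        if allele_a == allele_b:  # no alleles observed at all
            allele_a, allele_b = "A", UNOBSERVED_ALLELE
        variants.append(VariantRecord(chrom, snp_id, bp, allele_a, allele_b))
        if len(samples) == 0:
            continue
        miss = (t1 == "0") | (t2 == "0")
        dosage = (t1 == allele_b).astype(np.int8) + (t2 == allele_b).astype(np.int8)
        calls[:, j] = np.where(miss, MISSING_CALL, dosage)

    return GenotypeDataset(samples=samples, variants=variants, calls=calls)


def write_ped_map(
    dataset: GenotypeDataset, ped_path: str | Path, map_path: str | Path
) -> None:
    """Write a dataset back to PED/MAP so that re-reading reproduces it exactly."""
    with open(map_path, "w") as fh:
        for v in dataset.variants:
            fh.write(f"{v.chrom} {v.snp_id} 0 {v.bp}\n")

    with open(ped_path, "w") as fh:
        for i, s in enumerate(dataset.samples):
            pheno = "2" if s.status == CASE else "1"
            parts = [s.family_id, s.individual_id, "0", "0", "0", pheno]
            for j, v in enumerate(dataset.variants):
                c = dataset.calls[i, j]
                if c == MISSING_CALL:
                    parts += ["0", "0"]
                elif c == 0:
                    parts += [v.allele_a, v.allele_a]
                elif c == 1:
                    parts += [v.allele_a, v.allele_b]
                else:
                    parts += [v.allele_b, v.allele_b]
            fh.write(" ".join(parts) + "\n")


def read_item_scores(path: str | Path) -> pd.DataFrame:
    """Read a tab-delimited item-score table (rows = individuals, columns = items).

    Returns a float DataFrame where NaN marks an empty (missing) cell; all
    non-missing cells must be integer codes.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)

    def _cell(value: object, item: str) -> float:
        if value is None or (isinstance(value, float) and np.isnan(value)):
            return np.nan
        s = str(value).strip()
        if s == "":
            return np.nan
        try:
            return float(int(s))
        except ValueError:
            raise ValueError(
                f"{path}: non-integer cell {s!r} in column {item!r}"
            ) from None

    out = pd.DataFrame(
        {col: [_cell(v, col) for v in df[col]] for col in df.columns},
        index=df.index,
    )
    return out


def write_item_scores(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write an item-score table as TSV; missing values become empty cells."""
    formatted = matrix.map(lambda v: "" if pd.isna(v) else str(int(v)))
    formatted.index.name = matrix.index.name or "individual_id"
    formatted.to_csv(path, sep="\t")


#: association-table core columns, in output order
ASSOC_CORE_COLUMNS = ["CHR", "SNP", "BP", "A1", "F_A", "F_U", "A2", "CHISQ", "OR"]
ASSOC_P_COLUMNS = ["UNADJ", "FDR_BH", "BONF"]

_FREQ_COLS = {"F_A", "F_U"}
_TWO_DP_COLS = {"CHISQ", "OR"}


def _format_assoc_cell(col: str, value: object) -> str:
    if pd.isna(value):
        return "NA"
    if col in _FREQ_COLS:
        return f"{float(value):.3f}"
    if col in _TWO_DP_COLS:
        return f"{float(value):.2f}"
    if col in ASSOC_P_COLUMNS:
        return f"{float(value):.4f}"
    return str(value)


def write_assoc_table(rows: pd.DataFrame, path: str | Path) -> None:
    """Write association rows as TSV in the standard column layout.

    Column order: CHR SNP BP A1 F_A F_U A2 CHISQ OR, then any extra columns
    (annotation, subtype labels, counts), then UNADJ FDR_BH BONF.  Frequencies
    are printed to 3 decimals, CHISQ/OR to 2, p-values to 4.
    """
    extra = [
        c
        for c in rows.columns
        if c not in ASSOC_CORE_COLUMNS and c not in ASSOC_P_COLUMNS
    ]
    columns = (
        [c for c in ASSOC_CORE_COLUMNS if c in rows.columns]
        + extra
        + [c for c in ASSOC_P_COLUMNS if c in rows.columns]
    )
    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for _, row in rows.iterrows():
            fh.write(
                "\t".join(_format_assoc_cell(c, row[c]) for c in columns) + "\n"
            )
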