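"""Bundled worked-example association tables for an ASD subtype study.

Two published per-subtype allelic-association result tables are shipped as
plain TSV so the selection, replication, and statistic-reproduction
machinery can be exercised without access to the restricted genotype data
they were computed from:

* ``asd_subtype_final_assoc.tsv`` — the final-stage table of 18 unique
  trait-screened SNPs tested in four ASD subtypes (639/478/363/387 cases)
  against 2438 controls, with minor-allele frequencies, chi-square, OR and
  adjusted p-values per row;
* ``chr5p14_subtype_assoc.tsv`` — six previously reported chr5p14.1 SNPs
  re-tested per subtype and in the combined 1867-case group.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

_NUMERIC = ["BP", "F_A", "F_U", "CHISQ", "OR", "UNADJ", "FDR_BH", "BONF", "N_CASES"]


def _load(name: str) -> pd.DataFrame:
    ref = resources.files("stratqtl.data").joinpath(name)
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in _NUMERIC:
        if col in df.columns:
            df[col] = pd.to_numeric(df[col])
    return df


def load_subtype_final_assoc() -> pd.DataFrame:
    """Final-stage per-subtype association table (29 rows, 18 unique SNPs)."""
    return _load("asd_subtype_final_assoc.tsv")


def load_chr5p14_assoc() -> pd.DataFrame:
    """Per-subtype association of the six chr5p14.1 SNPs (replication check)."""
    return _load("chr5p14_subtype_assoc.tsv")
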