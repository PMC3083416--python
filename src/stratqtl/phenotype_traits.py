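"""Recode raw diagnostic item codes to 0-3 severities and build trait sums.

The ADI-R scores each of 123 interview items with small integer codes.  Codes
0-3 are ordinal severities (0 = normal, 3 = most severe); a handful of special
codes mark non-severity observations (7) or not-applicable/not-asked items
(8, 9).  Five behavioural categories — spoken language, non-verbal
communication, play skills, insistence on sameness, and social development —
are each defined by a list of items, and the per-individual sum of severities
within a category is the quantitative trait used for SNP screening.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: severity code that marks a missing value after recoding
MISSING = None

#: the five behavioural trait categories, in canonical order
TRAIT_NAMES = ("language", "nonverbal", "play", "sameness", "social")

#: default recode map: 0-3 pass through; 7 is a non-severity abnormality
#: (counted as 0); 8/9 are not-applicable/not-asked (missing).
DEFAULT_RECODE_MAP: dict[int, int | None] = {
    0: 0,
    1: 1,
    2: 2,
    3: 3,
    7: 0,
    8: None,
    9: None,
}


def recode_items(
    raw: pd.DataFrame, recode_map: Mapping[int, int | None] | None = None
) -> pd.DataFrame:
    """Map raw item codes to 0-3 severities (NaN = missing).

    Parameters
    ----------
    raw
        Individuals x items table of integer codes; NaN cells stay missing.
    recode_map
        code -> severity (0-3) or None (missing).  Defaults to
        :data:`DEFAULT_RECODE_MAP`.  Every code observed in ``raw`` must be
        covered.

    Raises
    ------
    ValueError
        If an observed code is not in the map, naming the code and the item.
    """
    rmap = dict(DEFAULT_RECODE_MAP if recode_map is None else recode_map)
    for severity in rmap.values():
        if severity is not None and severity not in (0, 1, 2, 3):
            raise ValueError(f"recode map severity {severity!r} outside 0-3")

    values = raw.to_numpy(dtype=float)
    observed = np.unique(values[~np.isnan(values)]).astype(int)
    for code in observed:
        if code not in rmap:
            hit = np.argwhere(values == code)[0]
            raise ValueError(
                f"unmapped item code {code} in item {raw.columns[hit[1]]!r} "
                f"(individual {raw.index[hit[0]]!r})"
            )

    out = np.full(raw.shape, np.nan)
    for code, severity in rmap.items():
        if severity is not None:
            out[values == code] = float(severity)
    return pd.DataFrame(out, index=raw.index, columns=raw.columns)


def trait_sums(
    matrix: pd.DataFrame,
    definitions: Mapping[str, Sequence[str]],
    max_missing_fraction: float = 0.2,
) -> pd.DataFrame:
    """Sum item severities per trait category (sum over observed items).

    A trait value is missing (NaN) for an individual whose fraction of
    missing items within that trait exceeds ``max_missing_fraction``; such
    individuals are excluded from quantitative-trait association for that
    trait.  Item lists may overlap between traits.

    Returns an individuals x traits DataFrame.
    """
    if not 0 <= max_missing_fraction <= 1:
        raise ValueError("max_missing_fraction must be in [0, 1]")
    out = {}
    for trait, items in definitions.items():
        items = list(items)
        if not items:
            raise ValueError(f"trait {trait!r} has an empty item list")
        unknown = [i for i in items if i not in matrix.columns]
        if unknown:
            raise ValueError(f"trait {trait!r} references unknown items {unknown}")
        sub = matrix[items]
        missing_frac = sub.isna().mean(axis=1)
        sums = sub.sum(axis=1, skipna=True)
        sums[missing_frac > max_missing_fraction] = np.nan
        out[trait] = sums
    return pd.DataFrame(out, index=matrix.index)


def read_trait_map(path: str) -> dict[str, list[str]]:
    """Parse a plain trait-map config: ``name = item1,item2,...`` per line.

    Blank lines and ``#`` comments are ignored.
    """
    definitions: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}: line {lineno}: expected 'name = items'")
            name, items = line.split("=", 1)
            definitions[name.strip()] = [
                item.strip() for item in items.split(",") if item.strip()
            ]
    if not definitions:
        raise ValueError(f"{path}: no trait definitions found")
    return definitions
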