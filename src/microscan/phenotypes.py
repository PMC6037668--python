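"""Questionnaire encoding, prevalence filtering and Phi correlation.

Binary phenotype statuses are represented throughout the package as a
samples x phenotypes :class:`pandas.DataFrame` of floats: 1.0 (positive),
0.0 (negative), NaN (unknown).  The encoders in this module map raw
questionnaire responses onto that representation:

* :func:`encode_any_yes` -- positive if any questionnaire answered yes,
  negative if only no answers, unknown if no data at all (the rule used
  for doctor-diagnosis questions asked repeatedly over the years);
* :func:`encode_ordinal_threshold` -- 0-4 frequency scales (used for
  constipation/cystitis-style items) dichotomized at 0-2 vs 3-4;
* :func:`encode_any_of` -- composite indicators (e.g. hearing loss from
  doctor diagnosis, self diagnosis or hearing-aid usage).

The Phi coefficient -- Pearson correlation specialized to two binaries --
is computed on pairwise-complete samples, with p-values from the
chi-square relation ``n * phi**2 ~ chi2(1)``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

POSITIVE = "positive"
NEGATIVE = "negative"
UNKNOWN = "unknown"

STATUS_TO_FLOAT = {POSITIVE: 1.0, NEGATIVE: 0.0, UNKNOWN: np.nan}

__all__ = [
    "POSITIVE", "NEGATIVE", "UNKNOWN", "STATUS_TO_FLOAT",
    "encode_any_yes", "encode_ordinal_threshold", "encode_any_of",
    "encode_long_table", "prevalence_filter",
    "phi_coefficient", "phi_matrix", "PhiMatrix",
]


def _is_missing(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    return isinstance(value, str) and value.lower() in {"missing", "na", ""}


def encode_any_yes(responses: Iterable) -> str:
    """Combine repeated yes/no questionnaire answers into one status."""
    seen_no = False
    result = UNKNOWN
    for r in responses:
        if _is_missing(r):
            continue
        level = str(r).lower()
        if level == "yes":
            return POSITIVE
        if level == "no":
            seen_no = True
        else:
            raise ValueError(f"unrecognized response level: {r!r}")
    return NEGATIVE if seen_no else result


def encode_ordinal_threshold(response) -> str:
    """Dichotomize a 0-4 frequency response: 0-2 negative, 3-4 positive."""
    if _is_missing(response):
        return UNKNOWN
    value = int(response)
    if value != response or not 0 <= value <= 4:
        raise ValueError(f"ordinal response must be an integer in 0..4, got {response!r}")
    return POSITIVE if value >= 3 else NEGATIVE


def encode_any_of(flags: Iterable) -> str:
    """Composite indicator: positive if any flag true, negative if all observed false."""
    seen_false = False
    for f in flags:
        if _is_missing(f):
            continue
        if isinstance(f, str):
            level = f.lower()
            if level not in {"true", "false"}:
                raise ValueError(f"unrecognized flag level: {f!r}")
            f = level == "true"
        if not isinstance(f, (bool, np.bool_)):
            raise ValueError(f"unrecognized flag level: {f!r}")
        if f:
            return POSITIVE
        seen_false = True
    return NEGATIVE if seen_false else UNKNOWN


def encode_long_table(
    long: pd.DataFrame,
    encoder=encode_any_yes,
    sample_col: str = "sample_id",
    phenotype_col: str = "phenotype",
    response_col: str = "response",
) -> pd.DataFrame:
    """Collapse a long-format questionnaire table to a wide status table."""
    wide = {}
    for (sample, pheno), grp in long.groupby([sample_col, phenotype_col], sort=True):
        status = encoder(grp[response_col].tolist())
        wide.setdefault(pheno, {})[sample] = STATUS_TO_FLOAT[status]
    df = pd.DataFrame(wide).sort_index()
    df.index.name = "sample_id"
    return df


def prevalence_filter(
    table: pd.DataFrame, reference_n: int, threshold: float = 0.01
) -> pd.DataFrame:
    """Retain phenotypes whose positive count reaches ``threshold`` of ``reference_n``.

    ``reference_n`` is the size of the wider cohort the prevalence is judged
    against (which may exceed the number of profiled samples).  Dropped
    phenotype names are recorded in ``result.attrs['dropped_phenotypes']``.
    """
    if reference_n <= 0:
        raise ValueError("reference_n must be positive")
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie strictly inside (0, 1)")
    positives = (table == 1.0).sum(axis=0)
    keep = positives / reference_n >= threshold
    dropped = sorted(table.columns[~keep])
    result = table.loc[:, keep].copy()
    result.attrs["dropped_phenotypes"] = dropped
    return result


def phi_coefficient(x, y) -> tuple[float, float, int]:
    """Phi on pairwise-complete samples with a chi-square p-value.

    Returns ``(phi, p_value, n)``; ``(nan, nan, n)`` with a warning when
    either vector is constant on the pairwise-complete subset.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = int(ok.sum())
    if n == 0 or x.min() == x.max() or y.min() == y.max():
        warnings.warn("phi undefined: constant vector after pairwise deletion")
        return (float("nan"), float("nan"), n)
    n11 = float(np.sum((x == 1) & (y == 1)))
    n10 = float(np.sum((x == 1) & (y == 0)))
    n01 = float(np.sum((x == 0) & (y == 1)))
    n00 = float(np.sum((x == 0) & (y == 0)))
    r1, r0 = n11 + n10, n01 + n00
    c1, c0 = n11 + n01, n10 + n00
    phi = (n11 * n00 - n10 * n01) / math.sqrt(r1 * r0 * c1 * c0)
    p = float(stats.chi2.sf(n * phi * phi, df=1))
    return (float(phi), p, n)


@dataclass
class PhiMatrix:
    """Pairwise Phi over phenotype pairs with companion p-value and count matrices."""

    phi: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame


def phi_matrix(table: pd.DataFrame) -> PhiMatrix:
    """All pairwise Phi coefficients of a status table, pairwise-complete."""
    cols = list(table.columns)
    if len(cols) < 2:
        raise ValueError("phi_matrix needs at least two phenotypes")
    k = len(cols)
    phi = np.eye(k)
    pval = np.full((k, k), np.nan)
    counts = np.zeros((k, k), dtype=int)
    values = table.to_numpy(dtype=float)
    for i in range(k):
        counts[i, i] = int(np.sum(~np.isnan(values[:, i])))
        for j in range(i + 1, k):
            f, p, n = phi_coefficient(values[:, i], values[:, j])
            phi[i, j] = phi[j, i] = f
            pval[i, j] = pval[j, i] = p
            counts[i, j] = counts[j, i] = n
    return PhiMatrix(
        phi=pd.DataFrame(phi, index=cols, columns=cols),
        p=pd.DataFrame(pval, index=cols, columns=cols),
        n=pd.DataFrame(counts, index=cols, columns=cols),
    )
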