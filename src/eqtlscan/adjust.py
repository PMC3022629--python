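"""Multiple-testing adjustment of per-SNP p-values.

Five procedures are offered: Bonferroni, Holm (step-down), Šidák
(single-step), Benjamini–Hochberg FDR and Benjamini–Yekutieli FDR.  The
adjustment family is the set of SNPs tested for one probe — each probe is a
separate analysis, so there is no cross-probe correction.  NaN inputs
(degenerate SNPs) are excluded from the test count m and preserved as NaN
in the output.

The arithmetic is delegated to :func:`statsmodels.stats.multitest.multipletests`;
this module adds validation, NaN masking and the fixed column order used in
the output tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .errors import DataError

#: method name -> statsmodels method code
METHODS = {
    "bonferroni": "bonferroni",
    "holm": "holm",
    "sidak": "sidak",
    "bh": "fdr_bh",
    "by": "fdr_by",
}

#: fixed column order for adjusted-p tables
COLUMN_ORDER = ("raw", "bonferroni", "holm", "sidak", "bh", "by")


@dataclass
class AdjustedPValues:
    """Adjusted p-values aligned with the input order.

    ``m`` is the number of non-NaN tests the correction was computed over.
    """

    method: str
    values: np.ndarray
    m: int


def _validate(p: np.ndarray) -> np.ndarray:
    mask = ~np.isnan(p)
    bad = p[mask]
    if ((bad <= 0) | (bad > 1)).any():
        offending = bad[(bad <= 0) | (bad > 1)]
        raise DataError(
            f"p-values must lie in (0, 1]; offending values include "
            f"{offending[:5].tolist()}"
        )
    return mask


def adjust(p: Sequence[float], method: str) -> AdjustedPValues:
    """Adjust a p-value vector by one named procedure.

    NaN entries stay NaN and do not count toward m.  Every adjusted value
    is >= its raw value and capped at 1.
    """
    if method not in METHODS:
        raise DataError(f"unknown method '{method}'; choose from {sorted(METHODS)}")
    p = np.asarray(p, dtype=float)
    mask = _validate(p)
    out = np.full(p.shape, np.nan)
    m = int(mask.sum())
    if m:
        with np.errstate(divide="ignore"):  # sidak hits log1p(-1) at p=1
            out[mask] = multipletests(p[mask], method=METHODS[method])[1]
        # guard against floating rounding below the raw value
        out[mask] = np.clip(np.maximum(out[mask], p[mask]), None, 1.0)
    return AdjustedPValues(method=method, values=out, m=m)


def adjust_all(p: Sequence[float], methods: Sequence[str] = tuple(METHODS)) -> pd.DataFrame:
    """Apply every requested method; columns in the fixed order raw-first."""
    p = np.asarray(p, dtype=float)
    _validate(p)
    data = {"raw": p}
    for name in COLUMN_ORDER[1:]:
        if name in methods:
            data[name] = adjust(p, name).values
    return pd.DataFrame(data)
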