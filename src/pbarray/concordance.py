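"""Microarray vs qRT-PCR fold-change concordance.

Fold changes from the two assays are compared on the log10 scale by
Pearson correlation; the coefficient of determination r² is the standard
summary of cross-platform agreement.  Roots and shoots are pooled into one
correlation by default, with per-tissue results alongside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .errors import DataError

log = logging.getLogger(__name__)


@dataclass
class ConcordanceResult:
    n_pairs: int
    r: float
    r2: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{"n": self.n_pairs, "r": self.r, "r2": self.r2}])


def concordance(pairs: pd.DataFrame) -> ConcordanceResult:
    """Pearson correlation of log10 fold changes between the two assays.

    ``pairs`` needs columns ``fc_array`` and ``fc_qpcr`` (positive linear
    ratios).  Rows with a missing value in either assay are dropped with a
    logged count.  Zero variance in either coordinate leaves r undefined
    (NaN).  Requires at least three complete pairs.
    """
    df = pairs[["fc_array", "fc_qpcr"]].copy()
    n_before = len(df)
    df = df.dropna()
    n_dropped = n_before - len(df)
    if n_dropped:
        log.info("concordance: dropped %d pairs with a missing fold change", n_dropped)
    if len(df) < 3:
        raise DataError(f"concordance needs >= 3 complete pairs, got {len(df)}")
    if not np.all(df.to_numpy() > 0):
        raise DataError("all fold changes must be > 0")
    x = np.log10(df["fc_array"].to_numpy())
    y = np.log10(df["fc_qpcr"].to_numpy())
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        log.warning("concordance undefined: zero variance in one coordinate")
        return ConcordanceResult(n_pairs=len(df), r=float("nan"), r2=float("nan"))
    r = float(pearsonr(x, y).statistic)
    return ConcordanceResult(n_pairs=len(df), r=r, r2=r * r)


def concordance_by_tissue(pairs: pd.DataFrame) -> pd.DataFrame:
    """Pooled plus per-tissue concordance as one table (scope column first)."""
    rows = [{"scope": "pooled", **concordance(pairs).to_frame().iloc[0].to_dict()}]
    if "tissue" in pairs.columns:
        for tissue, sub in pairs.groupby("tissue", sort=True):
            if len(sub) >= 3:
                res = concordance(sub)
                rows.append({"scope": str(tissue), **res.to_frame().iloc[0].to_dict()})
    return pd.DataFrame(rows)
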