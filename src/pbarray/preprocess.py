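"""Normalization and differential-expression calling.

The chain mirrors standard single-channel microarray practice for a
two-condition design: between-array upper-quartile scaling, per-probe
median centering, log transform, a background-retention rule, then a
pooled-variance Student t-test per gene with Benjamini-Hochberg FDR
control.  Fold changes are always reported on the linear scale as
treated/control ratios of normalized means.

"Quartile normalization" here is percentile-shift scaling: every array is
rescaled so its 75th percentile equals the geometric mean of the input
arrays' 75th percentiles (ratios within an array are preserved).  A full
quantile-normalization mode is available for sensitivity checks.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping

import numpy as np
import pandas as pd
import scipy.stats as st
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix, TISSUES, validate_de_table
from .errors import DataError, ParameterError


def _require_positive(m: ExpressionMatrix, op: str) -> None:
    if m.log_scale:
        raise DataError(f"{op} expects linear-scale intensities")
    if not np.all(m.values.to_numpy() > 0):
        raise DataError(f"{op}: all intensities must be > 0")


def quartile_normalize(m: ExpressionMatrix, mode: str = "upper_quartile") -> ExpressionMatrix:
    """Equalize arrays by their 75th-percentile intensity (default) or by full quantiles.

    Upper-quartile mode rescales each array so all arrays share a common
    75th percentile — the geometric mean of the input arrays' 75th
    percentiles — leaving within-array ratios untouched.  Percentiles use
    linear interpolation between order statistics.  Idempotent.
    """
    _require_positive(m, "quartile_normalize")
    v = m.values.to_numpy(dtype=float)
    if mode == "upper_quartile":
        q75 = np.quantile(v, 0.75, axis=0)
        target = float(np.exp(np.mean(np.log(q75))))
        out = v * (target / q75)
    elif mode == "quantile":
        # classic full quantile normalization: replace each array's sorted
        # values by the across-array mean of order statistics
        order = np.argsort(v, axis=0, kind="stable")
        ranks = np.empty_like(order)
        nrow = v.shape[0]
        ranks[order, np.arange(v.shape[1])] = np.arange(nrow)[:, None]
        means = np.sort(v, axis=0).mean(axis=1)
        out = means[ranks]
    else:
        raise ParameterError(f"unknown normalization mode: {mode!r}")
    return m.with_values(pd.DataFrame(out, index=m.values.index, columns=m.values.columns))


def median_center_probes(m: ExpressionMatrix) -> ExpressionMatrix:
    """Divide every probe row by its median across all samples (per-probe median -> 1)."""
    if m.n_samples < 1:
        raise DataError("median_center_probes needs at least one sample")
    med = m.values.median(axis=1)
    if (med == 0).any():
        raise DataError("probe with zero median")
    out = m.values.div(med, axis=0)
    return m.with_values(out)


def log_transform(m: ExpressionMatrix, base: float = 2) -> ExpressionMatrix:
    """Elementwise logarithm; default base 2 (microarray convention)."""
    _require_positive(m, "log_transform")
    out = np.log(m.values.to_numpy(dtype=float)) / np.log(base)
    return m.with_values(
        pd.DataFrame(out, index=m.values.index, columns=m.values.columns), log_scale=True
    )


def background_filter(
    m: ExpressionMatrix, background: float, species: str, tissue: str
) -> list[str]:
    """Probes kept for a species x tissue contrast by the background-retention rule.

    A probe is retained iff there exists a condition (control or treated)
    in which ALL replicates exceed the background floor; probes that never
    rise above background in any full condition carry no usable signal
    (for the non-model species, typically failed cross-species
    hybridization) and are removed before testing.
    """
    ctrl = m.sample_ids(species=species, tissue=tissue, treatment="control")
    trt = m.sample_ids(species=species, tissue=tissue, treatment="Pb")
    if not ctrl or not trt:
        raise DataError(f"background_filter: empty condition for ({species}, {tissue})")
    above_ctrl = (m.values[ctrl] > background).all(axis=1)
    above_trt = (m.values[trt] > background).all(axis=1)
    keep = above_ctrl | above_trt
    return list(m.values.index[keep])


def collapse_probes(m: ExpressionMatrix, probe_to_gene: Mapping[str, str]) -> ExpressionMatrix:
    """Represent each gene by its probe with the largest mean intensity across all samples."""
    genes = pd.Series({p: probe_to_gene[p] for p in m.probe_ids if p in probe_to_gene})
    missing = [p for p in m.probe_ids if p not in probe_to_gene]
    if missing:
        raise DataError(f"probes missing from annotation: {missing[:5]}")
    mean_int = m.values.mean(axis=1)
    best = (
        pd.DataFrame({"gene": genes, "mean": mean_int})
        .sort_values(["gene", "mean"], ascending=[True, False], kind="stable")
        .drop_duplicates("gene")
    )
    out = m.values.loc[best.index]
    out = out.set_axis(best["gene"].to_numpy(), axis=0).sort_index()
    out.index.name = "gene_id"
    return ExpressionMatrix(out, m.samples.loc[list(out.columns)], log_scale=m.log_scale)


def _pooled_ttest(a: np.ndarray, b: np.ndarray):
    """Vectorized two-sided pooled-variance Student t-test per row.

    Rows with zero pooled variance get p=1 when the means agree and p=0
    (flagged by the caller) when they differ, where the t statistic is
    degenerate.
    """
    n1, n2 = a.shape[1], b.shape[1]
    if n1 < 2 or n2 < 2:
        raise DataError("de_test needs >= 2 replicates per condition")
    m1, m2 = a.mean(axis=1), b.mean(axis=1)
    v1 = a.var(axis=1, ddof=1)
    v2 = b.var(axis=1, ddof=1)
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
    denom = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    zero = denom == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m2 - m1) / denom
    p = 2.0 * st.t.sf(np.abs(t), df)
    equal_means = m1 == m2
    p[zero & equal_means] = 1.0
    t[zero & equal_means] = 0.0
    p[zero & ~equal_means] = 0.0
    return t, p, zero & ~equal_means


def de_test(
    m: ExpressionMatrix,
    species: str,
    tissue: str,
    probes: Iterable[str] | None = None,
    probe_to_gene: Mapping[str, str] | None = None,
    fdr_threshold: float = 0.1,
    log_base: float = 2,
) -> pd.DataFrame:
    """Per-gene differential-expression table for one species x tissue contrast.

    Expects a normalized linear-scale matrix whose probes have passed
    :func:`background_filter` (pass them via ``probes``).  The t-test runs
    on log-scale values; the fold change is the ratio of linear-scale
    condition means; ``q`` is the Benjamini-Hochberg adjusted p-value over
    all genes tested within this scope and ``regulated`` means q below the
    FDR threshold.
    """
    if not (0 < fdr_threshold <= 1):
        raise ParameterError("fdr_threshold must be in (0, 1]")
    sub = m if probes is None else m.subset(probes=probes)
    ctrl = sub.sample_ids(species=species, tissue=tissue, treatment="control")
    trt = sub.sample_ids(species=species, tissue=tissue, treatment="Pb")
    if len(ctrl) < 2 or len(trt) < 2:
        raise DataError("de_test needs >= 2 replicates per condition")
    sub = sub.subset(samples=ctrl + trt)
    if probe_to_gene is not None:
        sub = collapse_probes(sub, probe_to_gene)

    lin_c = sub.values[ctrl].to_numpy(dtype=float)
    lin_t = sub.values[trt].to_numpy(dtype=float)
    log_c = np.log(lin_c) / np.log(log_base)
    log_t = np.log(lin_t) / np.log(log_base)
    _, p, zero_var = _pooled_ttest(log_c, log_t)

    mean_c = lin_c.mean(axis=1)
    mean_t = lin_t.mean(axis=1)
    fc = mean_t / mean_c
    q = multipletests(p, method="fdr_bh")[1] if len(p) else np.array([])
    regulated = q < fdr_threshold
    direction = np.where(regulated & (fc > 1), "up", np.where(regulated & (fc < 1), "down", "none"))

    de = pd.DataFrame(
        {
            "gene_id": sub.values.index.to_numpy(),
            "species": species,
            "tissue": tissue,
            "mean_control": mean_c,
            "mean_treated": mean_t,
            "fc": fc,
            "p": p,
            "q": q,
            "regulated": regulated,
            "direction": direction,
            "zero_variance": zero_var,
        }
    ).reset_index(drop=True)
    return validate_de_table(de)


def count_regulated(de: pd.DataFrame) -> tuple[int, int]:
    """(n_up, n_down) regulated genes of a DE table."""
    return int((de["direction"] == "up").sum()), int((de["direction"] == "down").sum())


def summarize_regulated(tables: Mapping) -> pd.DataFrame:
    """Per-species accounting of regulated genes across tissues.

    ``tables`` maps (species, tissue) to either a DE table or a precomputed
    ``(n_up, n_down)`` pair.  Returns one row per species with up/down
    counts per tissue, the species total, and each tissue's share of the
    total as a percentage rounded to one decimal (missing when the total
    is zero).
    """
    counts: dict[tuple[str, str], tuple[int, int]] = {}
    for key, val in tables.items():
        if isinstance(val, pd.DataFrame):
            counts[key] = count_regulated(val)
        else:
            up, down = val
            counts[key] = (int(up), int(down))
    species_seen = sorted({s for s, _ in counts}, key=str)
    rows = []
    for sp in species_seen:
        row: dict = {"species": sp}
        total = 0
        for tissue in TISSUES:
            up, down = counts.get((sp, tissue), (0, 0))
            row[f"up_{tissue}"] = up
            row[f"down_{tissue}"] = down
            total += up + down
        row["total"] = total
        for tissue in TISSUES:
            sub = row[f"up_{tissue}"] + row[f"down_{tissue}"]
            row[f"pct_{tissue}"] = round(100.0 * sub / total, 1) if total else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
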