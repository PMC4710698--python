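"""Functional-class over-representation by normed frequency with bootstrap scores.

For each functional class the statistic is the *normed frequency*

    (n in class, input / n classified, input) /
    (n in class, reference / n classified, reference)

i.e. the class's share of the classified input list relative to its share
of the classified reference list; 1 means no enrichment.  Genes may carry
several classes (multi-membership) or none (unclassified genes are
excluded from the denominators).  Stability is quantified by recomputing
the statistic on bootstrap resamples of the input list (default B=100):
the resample mean and standard deviation (reported as the bootstrap SE)
accompany the point estimate.  Significance is a two-sided hypergeometric
(Fisher-exact) test of the class count; classes with fewer than five input
genes are flagged small.
"""

from __future__ import annotations

import warnings
from collections.abc import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .errors import DataError, ParameterError

#: gene_id -> set of class labels
ClassMap = Mapping[str, set]


def class_map_from_annotation(annotation: pd.DataFrame) -> dict:
    """Build a gene -> classes map from an annotation table with a semicolon-separated column."""
    out: dict[str, set] = {}
    for gene, cls in zip(annotation["gene_id"], annotation["classes"].fillna("")):
        labels = {c.strip() for c in str(cls).split(";") if c.strip()}
        out.setdefault(gene, set()).update(labels)
    return out


def classify(genes: Iterable[str], cmap: ClassMap):
    """Per-class gene counts and the number of classified genes.

    Unknown genes count as unclassified; a multi-class gene contributes to
    every class it carries, so counts may sum to more than n_classified.
    """
    counts: dict[str, int] = {}
    n_classified = 0
    for g in genes:
        labels = cmap.get(g, set())
        if labels:
            n_classified += 1
            for c in labels:
                counts[c] = counts.get(c, 0) + 1
    return counts, n_classified


def normed_frequency(
    n_class_input: int,
    n_classified_input: int,
    n_class_reference: int,
    n_classified_reference: int,
) -> float:
    """The double-ratio class score; NaN with a warning when the reference class is empty."""
    if n_classified_input <= 0:
        raise ParameterError("n_classified_input must be > 0")
    if n_classified_reference <= 0:
        raise ParameterError("n_classified_reference must be > 0")
    if n_class_reference <= 0:
        warnings.warn("normed_frequency undefined for empty reference class", stacklevel=2)
        return float("nan")
    return (n_class_input / n_classified_input) / (n_class_reference / n_classified_reference)


def _membership(genes: list, classes: list, cmap: ClassMap):
    mem = np.zeros((len(genes), len(classes)), dtype=np.int64)
    for i, g in enumerate(genes):
        labels = cmap.get(g, set())
        for j, c in enumerate(classes):
            if c in labels:
                mem[i, j] = 1
    classified = np.array([1 if cmap.get(g, set()) else 0 for g in genes], dtype=np.int64)
    return mem, classified


def bootstrap_scores(
    genes: Iterable[str],
    cmap: ClassMap,
    reference: Iterable[str],
    B: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Bootstrap mean and SE of the normed frequency per class.

    The input list is resampled with replacement at its original size B
    times; duplicated genes count multiply in both the class count and the
    classified-gene denominator of the input ratio.  Reference fractions
    stay fixed.  The SE is the standard deviation of the B resampled
    scores.  Resamples where no gene is classified contribute no score.
    """
    if B < 2:
        raise ParameterError("B must be >= 2")
    genes = list(genes)
    if not genes:
        raise ParameterError("input gene list must be nonempty")
    reference = list(reference)
    ref_counts, ref_classified = classify(reference, cmap)
    if ref_classified == 0:
        raise DataError("reference list has no classified gene")
    classes = sorted(set(ref_counts) | {c for g in genes for c in cmap.get(g, set())})

    mem, classified = _membership(genes, classes, cmap)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(genes), size=(B, len(genes)))
    counts_b = mem[idx].sum(axis=1)  # B x n_classes
    nclassified_b = classified[idx].sum(axis=1)  # B

    rows = []
    for j, c in enumerate(classes):
        ref_frac = ref_counts.get(c, 0) / ref_classified
        if ref_frac == 0:
            rows.append({"class_label": c, "boot_mean": np.nan, "boot_se": np.nan})
            continue
        ok = nclassified_b > 0
        scores = (counts_b[ok, j] / nclassified_b[ok]) / ref_frac
        if scores.size == 0:
            rows.append({"class_label": c, "boot_mean": np.nan, "boot_se": np.nan})
            continue
        if np.all(scores == scores[0]):  # resample-invariant: SE exactly zero
            se = 0.0
        else:
            se = float(scores.std(ddof=1)) if scores.size > 1 else 0.0
        rows.append(
            {
                "class_label": c,
                "boot_mean": float(scores.mean()),
                "boot_se": se,
            }
        )
    return pd.DataFrame(rows).set_index("class_label")


def _two_sided_pvals(N: int, K: int, n: int) -> np.ndarray:
    """Two-sided hypergeometric p for every achievable count k.

    Support is k in [max(0, n+K-N), min(n, K)]; the two-sided p-value at k
    sums the pmf over all k' whose pmf does not exceed pmf(k) (the
    Fisher-exact convention), with a small relative tolerance for float
    ties.  Returned array is indexed by k - support_min.
    """
    lo = max(0, n + K - N)
    hi = min(n, K)
    ks = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(ks, N, K, n)
    order = np.argsort(pmf, kind="stable")
    csum = np.cumsum(pmf[order])
    pvals = np.empty_like(pmf)
    sorted_pmf = pmf[order]
    # rank of the largest pmf value still <= pmf(k)*(1+tol)
    thresholds = pmf * (1.0 + 1e-12)
    pos = np.searchsorted(sorted_pmf, thresholds, side="right") - 1
    pvals = csum[pos]
    return np.minimum(pvals, 1.0)


def over_representation_test(
    n_class_input: int,
    n_classified_input: int,
    n_class_reference: int,
    n_classified_reference: int,
) -> float:
    """Two-sided hypergeometric p-value for the class count in the input list.

    Models the classified input list as ``n_classified_input`` draws
    without replacement from the ``n_classified_reference`` classified
    reference genes of which ``n_class_reference`` carry the class.
    """
    k, n, K, N = n_class_input, n_classified_input, n_class_reference, n_classified_reference
    if not (0 <= k <= n and 0 <= K <= N):
        raise DataError("invalid hypergeometric counts")
    if n > N or k > K:
        raise DataError("input counts exceed reference counts")
    lo = max(0, n + K - N)
    if not (lo <= k <= min(n, K)):
        raise DataError(f"count {k} outside hypergeometric support")
    return float(_two_sided_pvals(N, K, n)[k - lo])


def enrichment_table(
    genes: Iterable[str],
    cmap: ClassMap,
    reference: Iterable[str],
    B: int = 100,
    seed: int = 0,
    alpha: float = 0.05,
    small_class_min: int = 5,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Full per-class enrichment table, sorted by normed frequency (descending).

    Columns: input/reference counts, normed_frequency, bootstrap mean/SE,
    hypergeometric p_value (optionally BH-corrected across classes),
    significance and small-class booleans, and a display ``flags`` column
    using the ``*`` (significant) / ``o`` (fewer than ``small_class_min``
    input genes) convention.
    """
    genes = list(dict.fromkeys(genes))  # de-duplicate, keep order
    reference = list(reference)
    in_counts, n_in = classify(genes, cmap)
    ref_counts, n_ref = classify(reference, cmap)
    if n_ref == 0:
        raise DataError("reference list has no classified gene")
    if n_in == 0:
        return pd.DataFrame(
            columns=[
                "class_label", "n_class_input", "n_classified_input",
                "n_class_reference", "n_classified_reference", "normed_frequency",
                "boot_mean", "boot_se", "p_value", "significant", "small_class", "flags",
            ]
        )
    boots = bootstrap_scores(genes, cmap, reference, B=B, seed=seed)
    rows = []
    for c in sorted(set(ref_counts) | set(in_counts)):
        k = in_counts.get(c, 0)
        K = ref_counts.get(c, 0)
        nf = normed_frequency(k, n_in, K, n_ref) if K > 0 else float("nan")
        try:
            p = over_representation_test(k, n_in, K, n_ref) if K > 0 else float("nan")
        except DataError:
            # input list not drawn from the reference (count outside support)
            p = float("nan")
        rows.append(
            {
                "class_label": c,
                "n_class_input": k,
                "n_classified_input": n_in,
                "n_class_reference": K,
                "n_classified_reference": n_ref,
                "normed_frequency": nf,
                "boot_mean": boots["boot_mean"].get(c, np.nan),
                "boot_se": boots["boot_se"].get(c, np.nan),
                "p_value": p,
                "small_class": k < small_class_min,
            }
        )
    out = pd.DataFrame(rows)
    if bh_correct and out["p_value"].notna().any():
        from statsmodels.stats.multitest import multipletests

        mask = out["p_value"].notna()
        adj = out["p_value"].copy()
        adj[mask] = multipletests(out.loc[mask, "p_value"], method="fdr_bh")[1]
        out["p_value"] = adj
    out["significant"] = out["p_value"] < alpha
    out["flags"] = out.apply(
        lambda r: ("*" if r["significant"] else "") + ("o" if r["small_class"] else ""), axis=1
    )
    return (
        out.sort_values("normed_frequency", ascending=False, kind="stable")
        .reset_index(drop=True)
        [
            [
                "class_label", "n_class_input", "n_classified_input",
                "n_class_reference", "n_classified_reference", "normed_frequency",
                "boot_mean", "boot_se", "p_value", "significant", "small_class", "flags",
            ]
        ]
    )
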