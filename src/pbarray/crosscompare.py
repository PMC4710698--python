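"""Two-species candidate-selection cascade.

Within each tissue the regulated genes of the tolerant and sensitive
species are partitioned (Venn): genes regulated in the tolerant species
only (Pb-specific), in the sensitive only, or in both (Pb-common, carrying
a sign pair ``++/--/+-/-+``, tolerant sign first).  Candidates in the
tolerant species are then selected in stages:

* specific genes: keep those with a twofold change (fc > 2 or fc < 0.5);
* common genes: first keep those whose tolerant/sensitive fold-change
  ratio exceeds twofold in either direction, then apply the same twofold
  fc filter in the tolerant species;
* candidates = retained specific ∪ retained common, partitioned by
  direction.

Thresholds are strict inequalities; boundary values are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import DataError, ParameterError


@dataclass
class VennPartition:
    """Species-comparison sets for one tissue."""

    tissue: str
    specific_tolerant: set = field(default_factory=set)
    specific_sensitive: set = field(default_factory=set)
    common: dict = field(default_factory=dict)  # gene -> sign pair in {++, --, +-, -+}

    @property
    def sign_counts(self) -> dict:
        out = {s: 0 for s in ("++", "--", "+-", "-+")}
        for s in self.common.values():
            out[s] += 1
        return out

    def summary(self) -> dict:
        return {
            "tissue": self.tissue,
            "specific_tolerant": len(self.specific_tolerant),
            "specific_sensitive": len(self.specific_sensitive),
            "common": len(self.common),
            "sign_counts": self.sign_counts,
        }


@dataclass
class CandidateSelection:
    """Accounting ledger of the selection cascade for one tissue."""

    tissue: str
    specific_total: int = 0
    specific_retained_up: set = field(default_factory=set)
    specific_retained_down: set = field(default_factory=set)
    common_total: int = 0
    common_ratio_pass: set = field(default_factory=set)
    common_retained_up: set = field(default_factory=set)
    common_retained_down: set = field(default_factory=set)

    @property
    def specific_retained(self) -> set:
        return self.specific_retained_up | self.specific_retained_down

    @property
    def common_retained(self) -> set:
        return self.common_retained_up | self.common_retained_down

    @property
    def candidates(self) -> set:
        return self.specific_retained | self.common_retained

    @property
    def candidate_up(self) -> int:
        return len(self.specific_retained_up) + len(self.common_retained_up)

    @property
    def candidate_down(self) -> int:
        return len(self.specific_retained_down) + len(self.common_retained_down)

    def accounting(self) -> pd.DataFrame:
        """Cascade accounting, one row per stage (the printed-table layout)."""
        rows = [
            ("specific", "total", self.specific_total, None, None),
            (
                "specific",
                "fc_filter",
                len(self.specific_retained),
                len(self.specific_retained_up),
                len(self.specific_retained_down),
            ),
            ("common", "total", self.common_total, None, None),
            ("common", "ratio_filter", len(self.common_ratio_pass), None, None),
            (
                "common",
                "fc_filter",
                len(self.common_retained),
                len(self.common_retained_up),
                len(self.common_retained_down),
            ),
            (
                "candidates",
                "union",
                len(self.candidates),
                self.candidate_up,
                self.candidate_down,
            ),
        ]
        return pd.DataFrame(
            rows, columns=["category", "stage", "n", "n_up", "n_down"]
        ).assign(tissue=self.tissue)


def _regulated_signs(de: pd.DataFrame) -> dict:
    reg = de[de["regulated"]]
    return dict(zip(reg["gene_id"], reg["direction"].map({"up": "+", "down": "-"})))


def venn_partition(de_tol: pd.DataFrame, de_sen: pd.DataFrame, tissue: str) -> VennPartition:
    """Partition regulated genes of one tissue into specific and common sets.

    Both DE tables must cover the same gene universe (genes tested in both
    species); a gene absent from one species cannot be classified.
    """
    u_tol = set(de_tol["gene_id"])
    u_sen = set(de_sen["gene_id"])
    if u_tol != u_sen:
        diff = sorted((u_tol ^ u_sen))
        raise DataError(f"mismatched gene universes; {len(diff)} unmatched ids, e.g. {diff[:5]}")
    s_tol = _regulated_signs(de_tol)
    s_sen = _regulated_signs(de_sen)
    both = set(s_tol) & set(s_sen)
    return VennPartition(
        tissue=tissue,
        specific_tolerant=set(s_tol) - both,
        specific_sensitive=set(s_sen) - both,
        common={g: s_tol[g] + s_sen[g] for g in both},
    )


def _check_thresholds(hi: float, lo: float) -> None:
    if not (hi > 1 > lo > 0):
        raise ParameterError(f"fold-change thresholds must satisfy hi > 1 > lo > 0, got {hi}, {lo}")


def fc_filter(genes: set, de: pd.DataFrame, hi: float = 2.0, lo: float = 0.5):
    """Split genes into (up, down) by strict fold-change thresholds; middles discarded."""
    _check_thresholds(hi, lo)
    fc = de.set_index("gene_id")["fc"]
    up = {g for g in genes if fc[g] > hi}
    down = {g for g in genes if fc[g] < lo}
    return up, down


def ratio_filter(
    common: set,
    de_tol: pd.DataFrame,
    de_sen: pd.DataFrame,
    hi: float = 2.0,
    lo: float = 0.5,
) -> set:
    """Keep common genes whose tolerant/sensitive linear FC ratio is > hi or < lo.

    The ratio is taken on linear fold changes regardless of direction
    agreement; a gene up in one species and down in the other can pass on
    the ratio alone.
    """
    _check_thresholds(hi, lo)
    fc_t = de_tol.set_index("gene_id")["fc"]
    fc_s = de_sen.set_index("gene_id")["fc"]
    out = set()
    for g in common:
        ratio = fc_t[g] / fc_s[g]
        if ratio > hi or ratio < lo:
            out.add(g)
    return out


def candidate_accounting(
    vp: VennPartition,
    de_tol: pd.DataFrame,
    de_sen: pd.DataFrame,
    fc_hi: float = 2.0,
    fc_lo: float = 0.5,
    ratio_hi: float = 2.0,
    ratio_lo: float = 0.5,
) -> CandidateSelection:
    """Run the full selection cascade for one tissue and fill the accounting ledger."""
    spec_up, spec_down = fc_filter(vp.specific_tolerant, de_tol, fc_hi, fc_lo)
    ratio_pass = ratio_filter(set(vp.common), de_tol, de_sen, ratio_hi, ratio_lo)
    common_up, common_down = fc_filter(ratio_pass, de_tol, fc_hi, fc_lo)
    return CandidateSelection(
        tissue=vp.tissue,
        specific_total=len(vp.specific_tolerant),
        specific_retained_up=spec_up,
        specific_retained_down=spec_down,
        common_total=len(vp.common),
        common_ratio_pass=ratio_pass,
        common_retained_up=common_up,
        common_retained_down=common_down,
    )


def tissue_overlap(roots: CandidateSelection, shoots: CandidateSelection) -> set:
    """Genes selected as candidates in both tissues."""
    return roots.candidates & shoots.candidates


def candidate_table(
    sel: CandidateSelection, de_tol: pd.DataFrame, de_sen: pd.DataFrame
) -> pd.DataFrame:
    """Flat candidate list: gene, tissue, origin (specific/common), both FCs, direction."""
    fc_t = de_tol.set_index("gene_id")["fc"]
    fc_s = de_sen.set_index("gene_id")["fc"]
    rows = []
    for origin, up, down in (
        ("specific", sel.specific_retained_up, sel.specific_retained_down),
        ("common", sel.common_retained_up, sel.common_retained_down),
    ):
        for direction, genes in (("up", up), ("down", down)):
            for g in sorted(genes):
                rows.append(
                    {
                        "gene_id": g,
                        "tissue": sel.tissue,
                        "origin": origin,
                        "fc_tol": float(fc_t[g]),
                        "fc_sen": float(fc_s[g]),
                        "direction": direction,
                    }
                )
    return pd.DataFrame(
        rows, columns=["gene_id", "tissue", "origin", "fc_tol", "fc_sen", "direction"]
    )
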