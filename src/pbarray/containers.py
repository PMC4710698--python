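"""In-memory containers for probe-level expression data.

The central object is :class:`ExpressionMatrix`: a probes x samples table of
positive hybridization intensities together with a sample sheet describing
each array (species, tissue, treatment, replicate).  Every preprocessing step
consumes and returns an ``ExpressionMatrix`` so stages compose freely.

Two species are compared on one array design (cross-species hybridization):
a metal-tolerant accumulator hybridized to the array of a related sensitive
model species.  Species labels are therefore the roles ``"tolerant"`` and
``"sensitive"`` rather than taxon names.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError

SPECIES = ("tolerant", "sensitive")
TISSUES = ("roots", "shoots")
TREATMENTS = ("control", "Pb")

SAMPLE_SHEET_COLUMNS = ("species", "tissue", "treatment", "replicate")


@dataclass
class ExpressionMatrix:
    """Probe intensities plus per-sample descriptors.

    Parameters
    ----------
    values
        DataFrame indexed by probe_id with one column per sample_id.
        Intensities must be positive before any log transform.
    samples
        Sample sheet indexed by sample_id with columns
        ``species, tissue, treatment, replicate``.  The descriptor tuple
        must be unique per sample.
    log_scale
        Whether ``values`` currently holds log-transformed intensities.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    log_scale: bool = False

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise DataError(f"duplicate probe_id values: {dups[:5]}")
        missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in self.samples.columns]
        if missing:
            raise DataError(f"sample sheet missing columns: {missing}")
        unmatched = [c for c in self.values.columns if c not in self.samples.index]
        if unmatched:
            raise DataError(f"matrix columns missing from sample sheet: {unmatched}")
        desc = self.samples.loc[list(self.values.columns), list(SAMPLE_SHEET_COLUMNS)]
        if desc.duplicated().any():
            raise DataError("sample descriptor (species, tissue, treatment, replicate) not unique")
        bad_species = set(desc["species"]) - set(SPECIES)
        bad_tissue = set(desc["tissue"]) - set(TISSUES)
        bad_treat = set(desc["treatment"]) - set(TREATMENTS)
        if bad_species or bad_tissue or bad_treat:
            raise DataError(
                f"unknown sample descriptors: species={bad_species or '{}'} "
                f"tissue={bad_tissue or '{}'} treatment={bad_treat or '{}'}"
            )
        if not self.log_scale and not np.all(self.values.to_numpy() > 0):
            raise DataError("all intensities must be > 0 on the linear scale")

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def sample_ids(
        self,
        species: str | None = None,
        tissue: str | None = None,
        treatment: str | None = None,
    ) -> list[str]:
        """Sample ids matching the given descriptors (None = any)."""
        mask = pd.Series(True, index=self.samples.index)
        if species is not None:
            mask &= self.samples["species"] == species
        if tissue is not None:
            mask &= self.samples["tissue"] == tissue
        if treatment is not None:
            mask &= self.samples["treatment"] == treatment
        keep = [s for s in self.values.columns if mask.loc[s]]
        return keep

    def subset(self, probes=None, samples=None) -> "ExpressionMatrix":
        """New matrix restricted to the given probe and/or sample ids."""
        v = self.values
        if probes is not None:
            v = v.loc[list(probes)]
        if samples is not None:
            v = v[list(samples)]
        return ExpressionMatrix(v, self.samples.loc[list(v.columns)], log_scale=self.log_scale)

    def with_values(self, values: pd.DataFrame, log_scale: bool | None = None) -> "ExpressionMatrix":
        return ExpressionMatrix(
            values,
            self.samples,
            log_scale=self.log_scale if log_scale is None else log_scale,
        )

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.copy(), self.samples.copy(), log_scale=self.log_scale)


#: Column order of a differential-expression table (one row per gene).
DE_COLUMNS = (
    "gene_id",
    "species",
    "tissue",
    "mean_control",
    "mean_treated",
    "fc",
    "p",
    "q",
    "regulated",
    "direction",
    "zero_variance",
)


def validate_de_table(de: pd.DataFrame) -> pd.DataFrame:
    """Check the DE-table contract (fc > 0, p/q ranges, direction consistency)."""
    missing = [c for c in DE_COLUMNS if c not in de.columns]
    if missing:
        raise DataError(f"DE table missing columns: {missing}")
    if not np.all(de["fc"].to_numpy() > 0):
        raise DataError("DE table fold changes must be > 0")
    p = de["p"].to_numpy()
    q = de["q"].to_numpy()
    if np.any(p < 0) or np.any(p > 1) or np.any(q < p - 1e-12):
        raise DataError("DE table requires 0 <= p <= 1 and q >= p")
    up = de["direction"] == "up"
    down = de["direction"] == "down"
    if not ((up == (de["regulated"] & (de["fc"] > 1))).all() and
            (down == (de["regulated"] & (de["fc"] < 1))).all()):
        raise DataError("DE table direction inconsistent with regulated flag and fc")
    return de
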