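"""Synthetic two-species microarray experiment generator.

Emulates a cross-species hybridization (CSH) study design: a Pb-tolerant
accumulator species and a Pb-sensitive model species, roots and shoots,
control vs Pb-treated, with replicated arrays.  Gene expression is
log-normal; treatment effects are planted multiplicatively on chosen genes;
each array carries a multiplicative scale jitter; and a configurable
fraction of probes is "dropped" for the tolerant (non-model) species —
signal at or below the background floor in every sample — mimicking probes
whose target sequence diverged too far to hybridize.

The generator returns the planted ground truth alongside the data so the
downstream normalization / differential-expression / candidate-selection
cascade can be scored for recovery and false-discovery proportion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, SPECIES, TISSUES, TREATMENTS
from .errors import ParameterError

DEFAULT_CLASS_LABELS = (
    "photosynthesis",
    "cell wall",
    "metal handling",
    "hormone metabolism",
    "stress",
    "transport",
    "protein",
    "RNA",
    "signalling",
    "misc",
)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic experiment.

    Replicate noise and array jitter standard deviations are on the log2
    scale; ``fc_planted`` is the linear fold-change magnitude applied to
    treated samples of planted genes (up: x fc, down: x 1/fc).
    ``dropout_rate`` is the fraction of probes silenced for the tolerant
    species (uniform signal in (0, background]), standing in for failed
    cross-species hybridization.  ``common_fraction`` of planted genes are
    regulated in both species (Pb-common); the rest respond in the tolerant
    species only (Pb-specific).
    """

    n_probes: int = 2000
    n_genes: int = 2000
    n_up: int = 50
    n_down: int = 50
    fc_planted: float = 4.0
    noise_sd: float = 0.2
    array_scale_sd: float = 0.1
    background: float = 50.0
    dropout_rate: float = 0.2
    n_replicates: int = 3
    seed: int = 0
    common_fraction: float = 0.0
    base_log2_mean: float = 10.0
    base_log2_sd: float = 1.5
    class_labels: tuple[str, ...] = DEFAULT_CLASS_LABELS
    multi_class_prob: float = 0.15
    unclassified_prob: float = 0.10

    def validate(self) -> None:
        if self.n_probes < 1:
            raise ParameterError("n_probes must be >= 1")
        if not (1 <= self.n_genes <= self.n_probes):
            raise ParameterError("n_genes must satisfy 1 <= n_genes <= n_probes")
        if self.n_up < 0 or self.n_down < 0:
            raise ParameterError("n_up and n_down must be >= 0")
        if self.n_up + self.n_down > self.n_genes:
            raise ParameterError("n_up + n_down must be <= n_genes")
        if not self.fc_planted > 1:
            raise ParameterError("fc_planted must be > 1")
        for name in ("noise_sd", "array_scale_sd", "base_log2_sd"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        for name in ("dropout_rate", "common_fraction", "multi_class_prob", "unclassified_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ParameterError(f"{name} must be in [0, 1]")
        if self.background <= 0:
            raise ParameterError("background must be > 0")
        if self.n_replicates < 1:
            raise ParameterError("n_replicates must be >= 1")
        if not self.class_labels:
            raise ParameterError("class_labels must be nonempty")


@dataclass
class Truth:
    """Planted ground truth: regulated gene sets per (species, tissue), dropped probes per species."""

    planted_up: dict = field(default_factory=dict)
    planted_down: dict = field(default_factory=dict)
    dropped_probes: dict = field(default_factory=dict)

    def regulated(self, species: str, tissue: str) -> set:
        return set(self.planted_up.get((species, tissue), set())) | set(
            self.planted_down.get((species, tissue), set())
        )

    def to_json(self) -> str:
        def enc(d):
            return {"|".join(k) if isinstance(k, tuple) else k: sorted(v) for k, v in d.items()}

        return json.dumps(
            {
                "planted_up": enc(self.planted_up),
                "planted_down": enc(self.planted_down),
                "dropped_probes": enc(self.dropped_probes),
            },
            indent=1,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "Truth":
        raw = json.loads(text)

        def dec(d, tup):
            return {
                (tuple(k.split("|")) if tup else k): set(v) for k, v in d.items()
            }

        return cls(
            planted_up=dec(raw["planted_up"], True),
            planted_down=dec(raw["planted_down"], True),
            dropped_probes=dec(raw["dropped_probes"], False),
        )


def _sample_id(species: str, tissue: str, treatment: str, rep: int) -> str:
    return f"{species}_{tissue}_{treatment}_{rep}"


def simulate_experiment(config: SimulationConfig):
    """Generate (ExpressionMatrix, annotation DataFrame, Truth) for one experiment.

    The annotation table has columns ``probe_id, gene_id, classes`` with
    classes semicolon-separated (possibly empty; genes may carry more than
    one functional class).  All randomness flows through one seeded
    generator, so a fixed config yields byte-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    probe_ids = [f"P{i:05d}" for i in range(config.n_probes)]
    gene_ids = [f"G{i:05d}" for i in range(config.n_genes)]
    # one probe per gene for the first n_genes probes; extra probes land on random genes
    probe_gene = list(gene_ids)
    if config.n_probes > config.n_genes:
        extra = rng.integers(0, config.n_genes, size=config.n_probes - config.n_genes)
        probe_gene += [gene_ids[i] for i in extra]
    gene_of_probe = dict(zip(probe_ids, probe_gene))

    # planted regulated genes per tissue (shared gene ids across species;
    # tolerant species always responds, sensitive only for the common fraction)
    planted_up: dict = {}
    planted_down: dict = {}
    planted_genes_any: set = set()
    for tissue in TISSUES:
        chosen = rng.choice(config.n_genes, size=config.n_up + config.n_down, replace=False)
        up = {gene_ids[i] for i in chosen[: config.n_up]}
        down = {gene_ids[i] for i in chosen[config.n_up:]}
        planted_up[("tolerant", tissue)] = up
        planted_down[("tolerant", tissue)] = down
        n_cu = int(round(config.common_fraction * len(up)))
        n_cd = int(round(config.common_fraction * len(down)))
        planted_up[("sensitive", tissue)] = set(sorted(up)[:n_cu])
        planted_down[("sensitive", tissue)] = set(sorted(down)[:n_cd])
        planted_genes_any |= up | down

    # dropout: tolerant-species probes silenced in every sample; never a planted gene
    n_drop = int(round(config.dropout_rate * config.n_probes))
    eligible = [p for p in probe_ids if gene_of_probe[p] not in planted_genes_any]
    if n_drop > len(eligible):
        raise ParameterError(
            "dropout_rate too high: only "
            f"{len(eligible)} non-planted probes available for {n_drop} dropouts"
        )
    dropped = set(rng.choice(eligible, size=n_drop, replace=False)) if n_drop else set()
    dropped_idx = np.array([p in dropped for p in probe_ids])

    truth = Truth(
        planted_up=planted_up,
        planted_down=planted_down,
        dropped_probes={"tolerant": dropped, "sensitive": set()},
    )

    base_log2 = rng.normal(config.base_log2_mean, config.base_log2_sd, size=config.n_genes)
    base = {g: 2.0 ** v for g, v in zip(gene_ids, base_log2)}
    probe_base = np.array([base[gene_of_probe[p]] for p in probe_ids])

    columns: dict[str, np.ndarray] = {}
    sheet_rows = []
    log2fc = np.log2(config.fc_planted)
    for species in SPECIES:
        for tissue in TISSUES:
            up = planted_up[(species, tissue)]
            down = planted_down[(species, tissue)]
            effect = np.zeros(config.n_probes)
            for i, p in enumerate(probe_ids):
                g = gene_of_probe[p]
                if g in up:
                    effect[i] = log2fc
                elif g in down:
                    effect[i] = -log2fc
            for treatment in TREATMENTS:
                mu = probe_base * (2.0 ** effect if treatment == "Pb" else 1.0)
                for rep in range(1, config.n_replicates + 1):
                    noise = rng.normal(0.0, config.noise_sd, size=config.n_probes)
                    scale = rng.normal(0.0, config.array_scale_sd)
                    vals = mu * 2.0 ** (noise + scale)
                    if species == "tolerant" and n_drop:
                        low = rng.uniform(
                            config.background * 1e-3, config.background, size=n_drop
                        )
                        vals = vals.copy()
                        vals[dropped_idx] = low
                    sid = _sample_id(species, tissue, treatment, rep)
                    columns[sid] = vals
                    sheet_rows.append(
                        {
                            "sample_id": sid,
                            "species": species,
                            "tissue": tissue,
                            "treatment": treatment,
                            "replicate": rep,
                        }
                    )

    values = pd.DataFrame(columns, index=pd.Index(probe_ids, name="probe_id"))
    samples = pd.DataFrame(sheet_rows).set_index("sample_id")
    matrix = ExpressionMatrix(values, samples)

    annotation = _annotate(rng, probe_ids, probe_gene, config)
    return matrix, annotation, truth


def _annotate(rng, probe_ids, probe_gene, config: SimulationConfig) -> pd.DataFrame:
    """Seeded categorical class assignment per gene; multi-membership allowed."""
    labels = list(config.class_labels)
    classes_of_gene: dict[str, list[str]] = {}
    for g in sorted(set(probe_gene)):
        if rng.random() < config.unclassified_prob:
            classes_of_gene[g] = []
            continue
        first = labels[rng.integers(0, len(labels))]
        cls = [first]
        if len(labels) > 1 and rng.random() < config.multi_class_prob:
            second = first
            while second == first:
                second = labels[rng.integers(0, len(labels))]
            cls.append(second)
        classes_of_gene[g] = cls
    return pd.DataFrame(
        {
            "probe_id": probe_ids,
            "gene_id": probe_gene,
            "classes": [";".join(classes_of_gene[g]) for g in probe_gene],
        }
    )


def simulate_qpcr(
    truth: Truth,
    de: pd.DataFrame,
    n_genes: int,
    noise_sd: float,
    seed: int,
) -> pd.DataFrame:
    """Emulate a qRT-PCR validation panel from an array DE table.

    Genes are sampled (without replacement) from the regulated rows of the
    DE table — the panel a validation experiment would pick — and the qPCR
    fold change is the array fold change perturbed by Gaussian noise on the
    log10 scale.  Returns columns ``gene_id, tissue, fc_array, fc_qpcr``.
    """
    if noise_sd < 0:
        raise ParameterError("noise_sd must be >= 0")
    if n_genes > len(de):
        raise ParameterError(f"n_genes={n_genes} exceeds available DE rows ({len(de)})")
    rng = np.random.default_rng(seed)
    pool = de[de["regulated"]] if de["regulated"].sum() >= n_genes else de
    pool = pool.sort_values(["tissue", "gene_id"]).reset_index(drop=True)
    pick = rng.choice(len(pool), size=n_genes, replace=False)
    sel = pool.iloc[np.sort(pick)]
    log10_fc = np.log10(sel["fc"].to_numpy())
    fc_qpcr = 10.0 ** (log10_fc + rng.normal(0.0, noise_sd, size=n_genes))
    return pd.DataFrame(
        {
            "gene_id": sel["gene_id"].to_numpy(),
            "tissue": sel["tissue"].to_numpy(),
            "fc_array": sel["fc"].to_numpy(),
            "fc_qpcr": fc_qpcr,
        }
    )
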