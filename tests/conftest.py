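"""Shared fixtures: tiny hand-built matrices and a small simulated experiment."""

import numpy as np
import pandas as pd
import pytest

import pbarray as pb


def make_matrix(values: np.ndarray, samples: pd.DataFrame, probe_prefix="P") -> pb.ExpressionMatrix:
    """Wrap a raw array + sample sheet into an ExpressionMatrix."""
    v = pd.DataFrame(
        values,
        index=pd.Index([f"{probe_prefix}{i}" for i in range(values.shape[0])], name="probe_id"),
        columns=samples.index,
    )
    return pb.ExpressionMatrix(v, samples)


def sheet(n_reps=3, species=("tolerant", "sensitive"), tissues=("roots", "shoots")) -> pd.DataFrame:
    rows = []
    for sp in species:
        for ti in tissues:
            for tr in ("control", "Pb"):
                for r in range(1, n_reps + 1):
                    sid = f"{sp}_{ti}_{tr}_{r}"
                    rows.append(
                        {"sample_id": sid, "species": sp, "tissue": ti,
                         "treatment": tr, "replicate": r}
                    )
    return pd.DataFrame(rows).set_index("sample_id")


@pytest.fixture(scope="session")
def sim_small():
    """One small simulated experiment reused across read-only tests."""
    cfg = pb.SimulationConfig(
        n_probes=400, n_genes=400, n_up=15, n_down=15, seed=11, dropout_rate=0.2
    )
    matrix, annotation, truth = pb.simulate_experiment(cfg)
    return cfg, matrix, annotation, truth


@pytest.fixture(scope="session")
def de_small(sim_small):
    """DE tables for all four species x tissue scopes of the small simulation."""
    cfg, matrix, annotation, _ = sim_small
    probe_to_gene = dict(zip(annotation["probe_id"], annotation["gene_id"]))
    mq = pb.quartile_normalize(matrix)
    centered = pb.median_center_probes(mq)
    tables = {}
    for sp in ("tolerant", "sensitive"):
        for ti in ("roots", "shoots"):
            keep = pb.background_filter(mq, cfg.background, sp, ti)
            tables[(sp, ti)] = pb.de_test(
                centered, sp, ti, probes=keep, probe_to_gene=probe_to_gene
            )
    return tables
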