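"""Shared fixtures: desk-scale synthetic datasets and compact model configs."""

from types import SimpleNamespace

import numpy as np
import pytest

from permutedds import experiments as ex
from permutedds import fingerprints as fp
from permutedds import synthetic_data as sd
from permutedds.cell_lines import normalize_expression
from permutedds.model import ConvEncoderConfig, FusionConfig


def build_dataset(cfg: sd.SyntheticConfig, n_bits: int = 256) -> SimpleNamespace:
    """Materialize drugs, profiles, labels and a FeatureStore for a config."""
    drugs = sd.generate_drugs(cfg.n_drugs, cfg.seed)
    expr, mut, panel = sd.generate_cell_panel(
        cfg.n_cells, cfg.g_expr, cfg.g_mut, cfg.seed + 1, cfg.mutation_rate
    )
    triples = fp.featurize_drug_table(drugs, n_bits_hashtt=n_bits, dims_map4=n_bits)
    trios = sd.generate_trios(
        cfg.n_records, [d for d, _ in drugs], list(expr.index), cfg.seed + 2
    )
    scores = sd.generate_labels(trios, triples, expr, cfg)
    records = [
        ex.SynergyRecord(a, b, c, float(s)) for (a, b, c), s in zip(trios, scores)
    ]
    store = ex.FeatureStore(triples, normalize_expression(expr, expr), mut)
    return SimpleNamespace(
        cfg=cfg, drugs=drugs, triples=triples, expr=expr, mut=mut,
        panel=panel, trios=trios, records=records, store=store,
    )


def compact_model_config(store: ex.FeatureStore, **overrides) -> "ex.ModelConfig":
    """A small but structurally faithful model for fast tests."""
    base = dict(
        conv=ConvEncoderConfig(out_dim=32),
        fusion=FusionConfig(feature_dim=32, hidden_dim=64, out_dim=32),
        head_hidden=16,
    )
    base.update(overrides)
    return store.model_config(**base)


@pytest.fixture(scope="session")
def small_dataset():
    """12 drugs x 6 cells, 150 records, 256-bit fingerprints."""
    cfg = sd.SyntheticConfig(
        n_drugs=12, n_cells=6, n_records=150, g_expr=24, g_mut=24, seed=7
    )
    return build_dataset(cfg, n_bits=256)


@pytest.fixture(scope="session")
def default_dataset():
    """The default synthetic study conditions: 20 drugs, 10 cells, 500 records."""
    return build_dataset(sd.SyntheticConfig(), n_bits=1024)


@pytest.fixture
def rng():
    return np.random.Generator(np.random.PCG64(12345))
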