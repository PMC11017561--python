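"""Split strategies, metrics, deduplication, ablation wiring, ranking."""

import numpy as np
import pytest
import scipy.stats
from sklearn.metrics import mean_squared_error, r2_score

from permutedds import experiments as ex
from permutedds.errors import (
    DataCoverageError,
    DegenerateInputError,
    InsufficientEntitiesError,
    UnknownVariantError,
)
from permutedds.model import PermuteDDS

from conftest import compact_model_config


def _toy_records(n_drugs=6, n_cells=4, seed=0):
    rng = np.random.Generator(np.random.PCG64(seed))
    records = []
    for i in range(n_drugs):
        for j in range(i + 1, n_drugs):
            for c in range(n_cells):
                records.append(
                    ex.SynergyRecord(f"d{i}", f"d{j}", f"c{c}", float(rng.normal()))
                )
    return records


def test_record_rejects_self_combination():
    with pytest.raises(ValueError):
        ex.SynergyRecord("d1", "d1", "c1", 0.0)


def test_dedupe_averages_swapped_orderings():
    records = [
        ex.SynergyRecord("a", "b", "c1", 10.0),
        ex.SynergyRecord("b", "a", "c1", 20.0),
        ex.SynergyRecord("a", "b", "c2", 5.0),
    ]
    with pytest.warns(UserWarning, match="duplicate"):
        out = ex.dedupe_records(records)
    assert len(out) == 2
    assert out[0].score == 15.0


def test_holdout_split_sizes_union_determinism():
    records = _toy_records()
    cv, ind = ex.holdout_split(records, frac=0.10, seed=4)
    assert len(ind) == round(0.10 * len(records))
    assert len(cv) + len(ind) == len(records)
    key = lambda r: (r.drug_a, r.drug_b, r.cell_id)
    assert sorted(map(key, cv + ind)) == sorted(map(key, records))
    cv2, ind2 = ex.holdout_split(records, frac=0.10, seed=4)
    assert [key(r) for r in ind] == [key(r) for r in ind2]


def test_random_folds_partition_evenly():
    records = _toy_records()[:10]
    plan = ex.make_split_plan(records, "random", k=5, seed=1)
    sizes = sorted(len(f) for f in plan.folds)
    assert sizes == [2, 2, 2, 2, 2]
    flat = sorted(i for f in plan.folds for i in f)
    assert flat == list(range(10))


def test_leave_cell_out_folds_share_no_cell():
    records = _toy_records(n_cells=7)
    plan = ex.make_split_plan(records, "leave_cell_out", k=5, seed=2)
    cell_sets = [
        {records[i].cell_id for i in fold} for fold in plan.folds
    ]
    for a in range(5):
        for b in range(a + 1, 5):
            assert not (cell_sets[a] & cell_sets[b])


def test_leave_combination_out_groups_both_orderings():
    # construct a 20-record toy set including both (A,B) and (B,A) rows
    rng = np.random.Generator(np.random.PCG64(3))
    base = _toy_records(n_drugs=5, n_cells=1)
    swapped = [
        ex.SynergyRecord(r.drug_b, r.drug_a, r.cell_id, r.score) for r in base
    ]
    records = base + swapped
    plan = ex.make_split_plan(records, "leave_combination_out", k=5, seed=3)
    fold_of = {}
    for f, fold in enumerate(plan.folds):
        for i in fold:
            fold_of[i] = f
    for i, r in enumerate(records):
        j = len(base) + i if i < len(base) else i - len(base)
        assert fold_of[i] == fold_of[j]
    pair_sets = [
        {records[i].combination for i in fold} for fold in plan.folds
    ]
    for a in range(5):
        for b in range(a + 1, 5):
            assert not (pair_sets[a] & pair_sets[b])


def test_too_few_entities_raises():
    records = _toy_records(n_drugs=6, n_cells=2)
    with pytest.raises(InsufficientEntitiesError):
        ex.make_split_plan(records, "leave_cell_out", k=5, seed=0)


def test_metrics_perfect_prediction():
    y = np.array([1.0, 2.0, 3.0, 4.0])
    rep = ex.compute_metrics(y, y)
    assert (rep.rmse, rep.r2, rep.pcc) == (0.0, 1.0, 1.0)


def test_metrics_perfect_anticorrelation(rng):
    y = rng.normal(size=20)
    rep = ex.compute_metrics(y, -y + 3.0)
    assert rep.pcc == pytest.approx(-1.0, abs=1e-12)


def test_metrics_match_reference_implementations(rng):
    for _ in range(20):
        t = rng.normal(size=20)
        p = rng.normal(size=20)
        rep = ex.compute_metrics(t, p)
        assert rep.rmse == pytest.approx(np.sqrt(mean_squared_error(t, p)), abs=1e-10)
        assert rep.r2 == pytest.approx(r2_score(t, p), abs=1e-10)
        assert rep.pcc == pytest.approx(scipy.stats.pearsonr(t, p)[0], abs=1e-10)


def test_metrics_degenerate_labels_raise():
    with pytest.raises(DegenerateInputError):
        ex.compute_metrics(np.ones(5), np.arange(5.0))


def test_coverage_error_for_unknown_entities(small_dataset):
    bad = [ex.SynergyRecord("NOPE", "ALSO_NOPE", "NOCELL", 1.0)]
    with pytest.raises(DataCoverageError):
        small_dataset.store.index_records(bad)


def test_variant_configs_select_heads(small_dataset):
    store = small_dataset.store
    assert ex.variant_config("only_hashtt", store).kinds == ("hashtt",)
    assert ex.variant_config("wo_maccs", store).kinds == ("hashtt", "map4")
    assert ex.variant_config("wo_permute_mlp", store).use_permute_mlp is False
    assert ex.variant_config("permutedds_L", store).encoder == "ff"
    with pytest.raises(UnknownVariantError):
        ex.variant_config("nonsense", store)


def test_single_head_model_predicts_its_own_head(small_dataset, rng):
    store = small_dataset.store
    cfg = compact_model_config(store, kinds=("hashtt",))
    model = PermuteDDS(cfg)
    frame = ex.predict_records(model, small_dataset.records[:8], store)
    np.testing.assert_allclose(frame["y_hat"], frame["y_t"], rtol=1e-6)
    assert frame["y_p"].isna().all() and frame["y_s"].isna().all()


def test_two_head_model_averages_two_heads(small_dataset):
    store = small_dataset.store
    cfg = compact_model_config(store, kinds=("hashtt", "map4"))
    model = PermuteDDS(cfg)
    frame = ex.predict_records(model, small_dataset.records[:8], store)
    np.testing.assert_allclose(
        frame["y_hat"], (frame["y_t"] + frame["y_p"]) / 2, rtol=1e-6
    )


def test_wo_permute_mlp_equals_identity_fusion(small_dataset):
    """Replacing the blocks by identity equals zeroing their residual branches."""
    store = small_dataset.store
    without = PermuteDDS(compact_model_config(store, use_permute_mlp=False, dtype="float64"))
    full = PermuteDDS(compact_model_config(store, dtype="float64"))
    # align every shared parameter, then cancel the fusion blocks
    state = {k: v for k, v in without.state_dict().items()}
    full_state = full.state_dict()
    for k in full_state:
        if k in state:
            full_state[k] = state[k]
    full.load_state_dict(full_state)
    for fsn in full.fsns:
        for block in fsn.blocks:
            block.zero_residual_branches()
    records = small_dataset.records[:10]
    a = ex.predict_records(without, records, store)["y_hat"]
    b = ex.predict_records(full, records, store)["y_hat"]
    np.testing.assert_allclose(a, b, atol=1e-12)


def test_rank_unmeasured_enumeration_and_order(small_dataset):
    store = small_dataset.store
    model = PermuteDDS(compact_model_config(store))
    drugs = store.drug_ids[:3]
    cells = store.cell_ids[:2]
    table = ex.rank_unmeasured(drugs, cells, [], model, store)
    assert len(table) == 3 * 2  # C(3,2) pairs x 2 cells
    assert (table["y_hat"].to_numpy()[:-1] >= table["y_hat"].to_numpy()[1:]).all()
    measured = [
        ex.SynergyRecord(a, b, c, 0.0)
        for a, b, c in zip(table["drug_a"], table["drug_b"], table["cell_line"])
    ]
    assert ex.rank_unmeasured(drugs, cells, measured, model, store).empty
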