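"""Training behaviour: determinism, signal recovery, split-strategy ordering."""

import numpy as np
import pytest

from permutedds import experiments as ex

from conftest import compact_model_config

FAST = ex.TrainConfig(max_epochs=8, val_frac=0.0)


def test_same_seed_gives_identical_weights(small_dataset):
    store = small_dataset.store
    cfg = compact_model_config(store)
    m1, _ = ex.train_model(small_dataset.records, store, cfg, FAST, seed=5)
    m2, _ = ex.train_model(small_dataset.records, store, cfg, FAST, seed=5)
    s1, s2 = m1.state_dict(), m2.state_dict()
    assert all(np.array_equal(s1[k], s2[k]) for k in s1)


def test_prediction_files_are_reproducible(small_dataset, tmp_path):
    store = small_dataset.store
    cfg = compact_model_config(store)
    paths = []
    for run in range(2):
        model, _ = ex.train_model(small_dataset.records, store, cfg, FAST, seed=6)
        frame = ex.predict_records(model, small_dataset.records[:30], store)
        path = tmp_path / f"pred{run}.csv"
        frame.to_csv(path, index=False)
        paths.append(path.read_bytes())
    assert paths[0] == paths[1]


def test_loss_decreases_on_small_overfit_set(small_dataset):
    store = small_dataset.store
    cfg = compact_model_config(store)
    records = small_dataset.records[:64]
    _, log = ex.train_model(
        records, store, cfg, ex.TrainConfig(max_epochs=25, val_frac=0.0), seed=7
    )
    losses = log["train_loss"]
    assert losses[-1] < 0.5 * losses[0]


def test_trained_model_beats_permuted_labels(small_dataset):
    store = small_dataset.store
    cfg = compact_model_config(store)
    train, test = ex.holdout_split(small_dataset.records, frac=0.2, seed=8)
    schedule = ex.TrainConfig(max_epochs=12, val_frac=0.0)

    model, _ = ex.train_model(train, store, cfg, schedule, seed=8)
    frame = ex.predict_records(model, test, store)
    pcc_real = ex.compute_metrics(frame["y_true"], frame["y_hat"]).pcc

    rng = np.random.Generator(np.random.PCG64(8))
    scores = rng.permutation([r.score for r in train])
    permuted = [
        ex.SynergyRecord(r.drug_a, r.drug_b, r.cell_id, float(s))
        for r, s in zip(train, scores)
    ]
    null_model, _ = ex.train_model(permuted, store, cfg, schedule, seed=8)
    null_frame = ex.predict_records(null_model, test, store)
    pcc_null = ex.compute_metrics(null_frame["y_true"], null_frame["y_hat"]).pcc

    assert pcc_real > pcc_null


def test_early_stopping_restores_best_weights(small_dataset):
    store = small_dataset.store
    cfg = compact_model_config(store)
    _, log = ex.train_model(
        small_dataset.records, store, cfg,
        ex.TrainConfig(max_epochs=10, val_frac=0.2, patience=2), seed=9,
    )
    assert log["best_epoch"] is not None
    assert len(log["val_loss"]) <= 10


def test_swap_augmented_model_is_approximately_symmetric(small_dataset):
    store = small_dataset.store
    cfg = compact_model_config(store)
    records = small_dataset.records
    model, _ = ex.train_model(
        records, store, cfg,
        ex.TrainConfig(max_epochs=12, val_frac=0.0, augment_swap=True), seed=10,
    )
    frame = ex.predict_records(model, records[:60], store)
    swapped = [
        ex.SynergyRecord(r.drug_b, r.drug_a, r.cell_id, r.score) for r in records[:60]
    ]
    frame_swapped = ex.predict_records(model, swapped, store)
    # soft symmetrization: swapped predictions track unswapped ones closely
    gap = np.abs(frame["y_hat"].to_numpy() - frame_swapped["y_hat"].to_numpy())
    spread = np.std([r.score for r in records])
    assert np.median(gap) < 0.25 * spread


def test_run_cv_cardinality_and_aggregation(small_dataset):
    store = small_dataset.store
    cfg = compact_model_config(store)
    result = ex.run_cv(
        small_dataset.records, "random", store, cfg,
        ex.TrainConfig(max_epochs=3, val_frac=0.0), seed=11, k=5,
    )
    assert len(result.fold_metrics) == 5
    assert result.aggregate.rmse == pytest.approx(
        np.mean([m.rmse for m in result.fold_metrics])
    )
    assert len(result.predictions) == len(small_dataset.records)


def test_random_split_outperforms_leave_combination_out(small_dataset):
    """Held-in combinations are easier than held-out ones (planted pair effects)."""
    store = small_dataset.store
    cfg = compact_model_config(store)
    schedule = ex.TrainConfig(max_epochs=8, val_frac=0.0)
    diffs = []
    for seed in (0, 1, 2):
        rand = ex.run_cv(small_dataset.records, "random", store, cfg, schedule, seed=seed, k=3)
        lco = ex.run_cv(
            small_dataset.records, "leave_combination_out", store, cfg, schedule, seed=seed, k=3
        )
        diffs.append(rand.aggregate.pcc - lco.aggregate.pcc)
    assert np.mean(diffs) > -0.05


def test_noise_study_cardinality_and_zero_sigma(small_dataset):
    store = small_dataset.store
    cfg = compact_model_config(store)
    result = ex.noise_study(
        small_dataset.records[:80], store, sigmas=[0.0, 0.5], mode="mul", seed=12,
        model_config=cfg, train_config=ex.TrainConfig(max_epochs=3, val_frac=0.0),
    )
    assert set(result) == {0.0, 0.5}
    assert result[0.0] == 1.0
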