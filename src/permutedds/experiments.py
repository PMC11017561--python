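"""Evaluation harness: splits, training loop, metrics, ablations, robustness.

The protocol mirrors the benchmark design for synergy regression: 90% of
the records feed a 5-fold cross-validation under one of three split
strategies (random, leave-cell-out, leave-combination-out) and the held-out
10% serve as an independent test set. Models are scored by RMSE, the
coefficient of determination R^2 = 1 - SSE/SST, and Pearson's correlation.

A drug *combination* is the unordered pair {drug_a, drug_b}: both
orderings of a pair land in the same leave-combination-out fold, and
duplicate orderings of the same trio are deduplicated by score averaging.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cell_lines as cl
from .errors import (
    DataCoverageError,
    DegenerateInputError,
    InsufficientEntitiesError,
    ShapeMismatchError,
    UnknownVariantError,
)
from .model import ModelConfig, PermuteDDS, PredictionTriple, mse_loss

STRATEGIES = ("random", "leave_cell_out", "leave_combination_out")
ABLATION_VARIANTS = (
    "full",
    "wo_hashtt",
    "wo_map4",
    "wo_maccs",
    "only_hashtt",
    "only_map4",
    "only_maccs",
    "wo_permute_mlp",
    "permutedds_L",
)


@dataclass(frozen=True)
class SynergyRecord:
    """One (drug A, drug B, cell line, synergy score) example."""

    drug_a: str
    drug_b: str
    cell_id: str
    score: float

    def __post_init__(self):
        if self.drug_a == self.drug_b:
            raise ValueError(f"a combination needs two distinct drugs, got {self.drug_a!r} twice")

    @property
    def combination(self) -> frozenset:
        return frozenset((self.drug_a, self.drug_b))


def dedupe_records(records: list[SynergyRecord]) -> list[SynergyRecord]:
    """Merge duplicate trios (either drug order) by averaging their scores."""
    groups: dict[tuple, list[SynergyRecord]] = {}
    order: list[tuple] = []
    for rec in records:
        key = (tuple(sorted((rec.drug_a, rec.drug_b))), rec.cell_id)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(rec)
    n_dup = len(records) - len(groups)
    if n_dup:
        warnings.warn(
            f"averaged {n_dup} duplicate trio row(s) (unordered drug pairs)",
            stacklevel=2,
        )
    out = []
    for key in order:
        grp = groups[key]
        first = grp[0]
        out.append(
            SynergyRecord(
                drug_a=first.drug_a,
                drug_b=first.drug_b,
                cell_id=first.cell_id,
                score=float(np.mean([g.score for g in grp])),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Splits
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitPlan:
    """Five-fold partition of record indices under one split strategy."""

    strategy: str
    folds: tuple[tuple[int, ...], ...]
    seed: int

    def train_test_indices(self, fold: int) -> tuple[np.ndarray, np.ndarray]:
        test = np.array(self.folds[fold], dtype=int)
        train = np.array(
            [i for f, idxs in enumerate(self.folds) if f != fold for i in idxs],
            dtype=int,
        )
        return train, test


def holdout_split(
    records: list[SynergyRecord], frac: float = 0.10, seed: int = 0
) -> tuple[list[SynergyRecord], list[SynergyRecord]]:
    """Split off ``round(frac * n)`` records as the independent test set."""
    if not 0 < frac < 1:
        raise ValueError("frac must be in (0, 1)")
    n = len(records)
    n_hold = int(round(frac * n))
    rng = np.random.Generator(np.random.PCG64(seed))
    perm = rng.permutation(n)
    hold = set(perm[:n_hold].tolist())
    cv = [records[i] for i in range(n) if i not in hold]
    independent = [records[i] for i in sorted(hold)]
    return cv, independent


def make_split_plan(
    records: list[SynergyRecord], strategy: str, k: int = 5, seed: int = 0
) -> SplitPlan:
    """Partition records into ``k`` folds under the requested strategy.

    * ``random`` — records are shuffled into near-equal folds.
    * ``leave_cell_out`` — the *cell-line set* is partitioned; a record's
      fold is its cell line's fold, so no fold shares a cell with another.
    * ``leave_combination_out`` — the set of unordered drug pairs is
      partitioned; both orderings of a pair fall in the same fold.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}")
    if not records:
        raise ValueError("records must be non-empty")
    rng = np.random.Generator(np.random.PCG64(seed))
    if strategy == "random":
        parts = np.array_split(rng.permutation(len(records)), k)
        folds = tuple(tuple(int(i) for i in part) for part in parts)
        return SplitPlan(strategy=strategy, folds=folds, seed=seed)

    if strategy == "leave_cell_out":
        entity_of = lambda r: r.cell_id
    else:
        entity_of = lambda r: tuple(sorted((r.drug_a, r.drug_b)))
    entities = sorted({entity_of(r) for r in records}, key=str)
    if len(entities) < k:
        raise InsufficientEntitiesError(
            f"{strategy} needs >= {k} distinct entities, found {len(entities)}"
        )
    parts = np.array_split(rng.permutation(len(entities)), k)
    fold_of = {}
    for f, part in enumerate(parts):
        for e in part:
            fold_of[entities[int(e)]] = f
    folds: list[list[int]] = [[] for _ in range(k)]
    for i, rec in enumerate(records):
        folds[fold_of[entity_of(rec)]].append(i)
    return SplitPlan(strategy=strategy, folds=tuple(tuple(f) for f in folds), seed=seed)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MetricsReport:
    rmse: float
    r2: float
    pcc: float

    def as_dict(self) -> dict[str, float]:
        return {"rmse": self.rmse, "r2": self.r2, "pcc": self.pcc}


def compute_metrics(y_true, y_pred) -> MetricsReport:
    """RMSE, coefficient of determination, Pearson correlation."""
    t = np.asarray(y_true, dtype=float)
    p = np.asarray(y_pred, dtype=float)
    if t.shape != p.shape or t.ndim != 1:
        raise ShapeMismatchError(f"need equal-length 1-D vectors, got {t.shape}, {p.shape}")
    if t.size < 2:
        raise DegenerateInputError("metrics need at least 2 observations")
    sst = float(np.sum((t - t.mean()) ** 2))
    if sst == 0:
        raise DegenerateInputError("constant y_true: PCC and R^2 are undefined")
    sse = float(np.sum((t - p) ** 2))
    rmse = float(np.sqrt(sse / t.size))
    r2 = 1.0 - sse / sst
    if np.array_equal(t, p):  # exact by definition, immune to sqrt round-off
        pcc = 1.0
    else:
        dp = p - p.mean()
        dt = t - t.mean()
        denom = float(np.sqrt(np.sum(dt**2)) * np.sqrt(np.sum(dp**2)))
        pcc = float(np.sum(dt * dp) / denom) if denom > 0 else 0.0
    return MetricsReport(rmse=rmse, r2=r2, pcc=pcc)


# ---------------------------------------------------------------------------
# Feature store
# ---------------------------------------------------------------------------

class FeatureStore:
    """Dense feature matrices plus id -> row-index maps for fast training.

    Holds one (n_drugs, L_kind) 0/1 matrix per fingerprint kind and the
    (n_cells, g) expression / mutation matrices. Expression is expected to
    be normalized by the caller (z-scores fit on the training fold).
    """

    def __init__(
        self,
        fingerprint_triples: dict,
        expression: pd.DataFrame,
        mutation: pd.DataFrame,
    ):
        if list(expression.index) != list(mutation.index):
            raise ValueError("expression and mutation matrices must share cell order")
        self.drug_ids = sorted(fingerprint_triples)
        self.cell_ids = list(expression.index)
        self._drug_index = {d: i for i, d in enumerate(self.drug_ids)}
        self._cell_index = {c: i for i, c in enumerate(self.cell_ids)}
        kinds = ("hashtt", "map4", "maccs")
        self._fp = {
            kind: np.stack(
                [
                    np.asarray(fingerprint_triples[d][k].values, dtype=float)
                    for d in self.drug_ids
                ]
            )
            for k, kind in enumerate(kinds)
        }
        self._expr = expression.to_numpy(dtype=float)
        self._mut = mutation.to_numpy(dtype=float)

    def fp_matrix(self, kind: str) -> np.ndarray:
        return self._fp[kind]

    def expr_matrix(self) -> np.ndarray:
        return self._expr

    def mut_matrix(self) -> np.ndarray:
        return self._mut

    def fp_length(self, kind: str) -> int:
        return self._fp[kind].shape[1]

    @property
    def g_expr(self) -> int:
        return self._expr.shape[1]

    @property
    def g_mut(self) -> int:
        return self._mut.shape[1]

    def drug_index(self, drug_id: str) -> int:
        try:
            return self._drug_index[drug_id]
        except KeyError:
            raise DataCoverageError(f"drug {drug_id!r} has no fingerprints") from None

    def cell_index(self, cell_id: str) -> int:
        try:
            return self._cell_index[cell_id]
        except KeyError:
            raise DataCoverageError(f"cell line {cell_id!r} has no profile") from None

    def index_records(self, records: list[SynergyRecord]):
        idx_a = np.array([self.drug_index(r.drug_a) for r in records], dtype=int)
        idx_b = np.array([self.drug_index(r.drug_b) for r in records], dtype=int)
        idx_c = np.array([self.cell_index(r.cell_id) for r in records], dtype=int)
        y = np.array([r.score for r in records], dtype=float)
        return idx_a, idx_b, idx_c, y

    def with_noisy_profiles(self, sigma: float, mode: str, seed: int) -> "FeatureStore":
        """A copy whose expression *and* mutation matrices carry Gaussian noise."""
        clone = FeatureStore.__new__(FeatureStore)
        clone.drug_ids = self.drug_ids
        clone.cell_ids = self.cell_ids
        clone._drug_index = self._drug_index
        clone._cell_index = self._cell_index
        clone._fp = self._fp
        clone._expr = cl.noise_matrix(self._expr, sigma, mode, seed)
        clone._mut = cl.noise_matrix(self._mut, sigma, mode, seed + 1)
        return clone

    def model_config(self, **overrides) -> ModelConfig:
        """A ModelConfig whose input lengths match this store."""
        base = dict(
            fp_lengths={k: self.fp_length(k) for k in ("hashtt", "map4", "maccs")},
            expr_len=self.g_expr,
            mut_len=self.g_mut,
        )
        base.update(overrides)
        return ModelConfig(**base)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrainConfig:
    """Mini-batch Adam schedule.

    ``val_frac = 0`` disables early stopping; ``stop_loss`` halts training
    once the mean epoch loss drops below it (overfitting fixtures);
    ``augment_swap`` adds the drug-order-swapped copy of every training
    record, a soft symmetrization of the pair representation.
    """

    lr: float = 1e-3
    batch_size: int = 128
    max_epochs: int = 200
    patience: int = 20
    val_frac: float = 0.1
    stop_loss: float | None = None
    augment_swap: bool = False


def train_model(
    train_records: list[SynergyRecord],
    store: FeatureStore,
    model_config: ModelConfig,
    train_config: TrainConfig | None = None,
    seed: int = 0,
) -> tuple[PermuteDDS, dict]:
    """Train by mini-batch gradient descent on the MSE of the averaged head.

    Deterministic given ``seed`` (weights, batch order and the inner
    validation split all derive from it). When ``val_frac > 0`` an inner
    validation split drives early stopping with the configured patience and
    the best-validation weights are restored.
    """
    if not train_records:
        raise ValueError("training set is empty")
    cfg = train_config or TrainConfig()
    idx_a, idx_b, idx_c, y = store.index_records(train_records)
    if cfg.augment_swap:
        idx_a, idx_b = np.concatenate([idx_a, idx_b]), np.concatenate([idx_b, idx_a])
        idx_c = np.concatenate([idx_c, idx_c])
        y = np.concatenate([y, y])

    rng = np.random.Generator(np.random.PCG64(seed))
    n = len(y)
    n_val = int(round(cfg.val_frac * n)) if cfg.val_frac > 0 else 0
    use_early_stop = 0 < n_val < n
    perm = rng.permutation(n)
    val_idx = perm[:n_val] if use_early_stop else np.array([], dtype=int)
    fit_idx = perm[n_val:] if use_early_stop else np.arange(n)

    model = PermuteDDS(dataclasses.replace(model_config, seed=seed))
    from .nn import Adam

    optimizer = Adam(model.parameters(), lr=cfg.lr)
    log: dict = {"train_loss": [], "val_loss": [], "best_epoch": None}
    best_val = np.inf
    best_state = None
    patience_left = cfg.patience

    def eval_loss(sub) -> float:
        preds = _predict_indices(model, store, idx_a[sub], idx_b[sub], idx_c[sub])
        return mse_loss(y[sub], preds)

    for epoch in range(cfg.max_epochs):
        order = rng.permutation(fit_idx)
        epoch_losses = []
        for start in range(0, len(order), cfg.batch_size):
            batch = order[start : start + cfg.batch_size]
            optimizer.zero_grad()
            y_hat, _ = model.forward_indexed(store, idx_a[batch], idx_b[batch], idx_c[batch])
            loss = mse_loss(y[batch].astype(y_hat.dtype), y_hat)
            loss.backward()
            optimizer.step()
            epoch_losses.append(float(loss.data))
        log["train_loss"].append(float(np.mean(epoch_losses)))
        if cfg.stop_loss is not None and log["train_loss"][-1] <= cfg.stop_loss:
            break
        if use_early_stop:
            v = eval_loss(val_idx)
            log["val_loss"].append(v)
            if v < best_val:
                best_val = v
                best_state = model.state_dict()
                log["best_epoch"] = epoch
                patience_left = cfg.patience
            else:
                patience_left -= 1
                if patience_left <= 0:
                    break
    if best_state is not None:
        model.load_state_dict(best_state)
    return model, log


def _predict_indices(model, store, idx_a, idx_b, idx_c, batch_size: int = 512) -> np.ndarray:
    out = np.empty(len(idx_a))
    for start in range(0, len(idx_a), batch_size):
        sl = slice(start, start + batch_size)
        y_hat, _ = model.forward_indexed(store, idx_a[sl], idx_b[sl], idx_c[sl])
        out[sl] = np.asarray(y_hat.data, dtype=float)
    return out


def predict_records(
    model: PermuteDDS, records: list[SynergyRecord], store: FeatureStore
) -> pd.DataFrame:
    """Per-record predictions with the per-head scores.

    Columns: drug_a, drug_b, cell_line, y_true, y_hat, y_t, y_p, y_s (absent
    heads are NaN).
    """
    idx_a, idx_b, idx_c, y = store.index_records(records)
    head_cols = {"hashtt": "y_t", "map4": "y_p", "maccs": "y_s"}
    rows = {c: np.full(len(records), np.nan) for c in ("y_hat", "y_t", "y_p", "y_s")}
    for start in range(0, len(records), 512):
        sl = slice(start, start + 512)
        y_hat, per_kind = model.forward_indexed(store, idx_a[sl], idx_b[sl], idx_c[sl])
        rows["y_hat"][sl] = np.asarray(y_hat.data, dtype=float)
        for kind, tensor in per_kind.items():
            rows[head_cols[kind]][sl] = np.asarray(tensor.data, dtype=float)
    return pd.DataFrame(
        {
            "drug_a": [r.drug_a for r in records],
            "drug_b": [r.drug_b for r in records],
            "cell_line": [r.cell_id for r in records],
            "y_true": y,
            **rows,
        }
    )


# ---------------------------------------------------------------------------
# Cross-validation, ablations, robustness, ranking
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    plan: SplitPlan
    fold_metrics: list[MetricsReport]
    aggregate: MetricsReport
    pooled: MetricsReport
    predictions: pd.DataFrame  # all folds, with a "fold" column


def run_cv(
    records: list[SynergyRecord],
    strategy: str,
    store: FeatureStore,
    model_config: ModelConfig,
    train_config: TrainConfig | None = None,
    seed: int = 0,
    k: int = 5,
) -> CVResult:
    """k-fold cross-validation under one split strategy.

    The aggregate report is the arithmetic mean of the per-fold metrics;
    pooled metrics over the concatenated fold predictions are also computed.
    """
    plan = make_split_plan(records, strategy, k=k, seed=seed)
    fold_metrics = []
    frames = []
    for fold in range(k):
        train_idx, test_idx = plan.train_test_indices(fold)
        model, _ = train_model(
            [records[i] for i in train_idx], store, model_config, train_config,
            seed=seed + fold,
        )
        frame = predict_records(model, [records[i] for i in test_idx], store)
        frame["fold"] = fold
        frames.append(frame)
        fold_metrics.append(compute_metrics(frame["y_true"], frame["y_hat"]))
    predictions = pd.concat(frames, ignore_index=True)
    aggregate = MetricsReport(
        rmse=float(np.mean([m.rmse for m in fold_metrics])),
        r2=float(np.mean([m.r2 for m in fold_metrics])),
        pcc=float(np.mean([m.pcc for m in fold_metrics])),
    )
    pooled = compute_metrics(predictions["y_true"], predictions["y_hat"])
    return CVResult(plan, fold_metrics, aggregate, pooled, predictions)


def variant_config(variant: str, store: FeatureStore, **overrides) -> ModelConfig:
    """ModelConfig for one ablation variant."""
    if variant not in ABLATION_VARIANTS:
        raise UnknownVariantError(f"unknown ablation variant {variant!r}")
    kinds = ("hashtt", "map4", "maccs")
    opts: dict = {}
    if variant.startswith("wo_") and variant != "wo_permute_mlp":
        opts["kinds"] = tuple(k for k in kinds if k != variant[3:])
    elif variant.startswith("only_"):
        opts["kinds"] = (variant[5:],)
    elif variant == "wo_permute_mlp":
        opts["use_permute_mlp"] = False
    elif variant == "permutedds_L":
        opts["encoder"] = "ff"
    opts.update(overrides)
    return store.model_config(**opts)


def run_ablation(
    variant: str,
    records: list[SynergyRecord],
    store: FeatureStore,
    seed: int = 0,
    train_config: TrainConfig | None = None,
    test_frac: float = 0.2,
    **config_overrides,
) -> MetricsReport:
    """Train one ablation variant on a seeded random split and score the rest."""
    cfg = variant_config(variant, store, **config_overrides)
    train, test = holdout_split(records, frac=test_frac, seed=seed)
    model, _ = train_model(train, store, cfg, train_config, seed=seed)
    frame = predict_records(model, test, store)
    return compute_metrics(frame["y_true"], frame["y_hat"])


def noise_study(
    records: list[SynergyRecord],
    store: FeatureStore,
    sigmas: list[float],
    mode: str,
    seed: int = 0,
    model_config: ModelConfig | None = None,
    train_config: TrainConfig | None = None,
    test_frac: float = 0.2,
) -> dict[float, float]:
    """Robustness to noisy cell-line profiles.

    For each sigma, the model is retrained on profiles carrying
    multiplicative (``x * N(1, sigma)``) or additive (``x + N(0, sigma)``)
    Gaussian noise and its predictions on a common clean test split are
    correlated (Pearson) with those of the noiseless-trained model. With
    sigma = 0 and a shared seed the two trainings are identical, so the
    correlation is exactly 1.
    """
    if any(s < 0 for s in sigmas):
        raise ValueError("sigmas must be >= 0")
    cfg = model_config or store.model_config()
    train, test = holdout_split(records, frac=test_frac, seed=seed)
    reference, _ = train_model(train, store, cfg, train_config, seed=seed)
    ref_pred = predict_records(reference, test, store)["y_hat"].to_numpy()
    out: dict[float, float] = {}
    for sigma in sigmas:
        noisy_store = store.with_noisy_profiles(sigma, mode, seed=seed)
        model, _ = train_model(train, noisy_store, cfg, train_config, seed=seed)
        pred = predict_records(model, test, store)["y_hat"].to_numpy()
        out[float(sigma)] = compute_metrics(ref_pred, pred).pcc if sigma > 0 else (
            1.0 if np.array_equal(ref_pred, pred) else compute_metrics(ref_pred, pred).pcc
        )
    return out


def rank_unmeasured(
    drug_ids: list[str],
    cell_ids: list[str],
    measured_records: list[SynergyRecord],
    model: PermuteDDS,
    store: FeatureStore,
) -> pd.DataFrame:
    """Predict and rank every unmeasured (unordered pair, cell) trio.

    Rows are sorted by predicted score descending; ties break
    lexicographically by (drug_a, drug_b, cell_line).
    """
    measured = {
        (tuple(sorted((r.drug_a, r.drug_b))), r.cell_id) for r in measured_records
    }
    candidates = []
    for i, a in enumerate(sorted(drug_ids)):
        for b in sorted(drug_ids)[i + 1 :]:
            for c in cell_ids:
                if ((a, b), c) not in measured:
                    candidates.append((a, b, c))
    if not candidates:
        return pd.DataFrame(columns=["drug_a", "drug_b", "cell_line", "y_hat"])
    idx_a = np.array([store.drug_index(a) for a, _, _ in candidates])
    idx_b = np.array([store.drug_index(b) for _, b, _ in candidates])
    idx_c = np.array([store.cell_index(c) for _, _, c in candidates])
    y_hat = _predict_indices(model, store, idx_a, idx_b, idx_c)
    frame = pd.DataFrame(
        {
            "drug_a": [a for a, _, _ in candidates],
            "drug_b": [b for _, b, _ in candidates],
            "cell_line": [c for _, _, c in candidates],
            "y_hat": y_hat,
        }
    )
    return frame.sort_values(
        by=["y_hat", "drug_a", "drug_b", "cell_line"],
        ascending=[False, True, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
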