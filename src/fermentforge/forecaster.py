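"""Variable-depth LSTM forecasting of fermentation time series.

The forecaster consumes a historical window of ``nt`` samples of the
``k = 6`` fermentation attributes and predicts the next ``pl`` samples
of all attributes (default nt = pl = 288 five-minute steps, i.e. 24 h
in → 24 h out).  Attributes are min–max normalized to [0, 1] with
bounds fitted on the training curves; the architecture's width (cells
per layer) and depth (layer count) are auto-tuned in two stages by
seeded random search on validation RMSE, with a layer-count penalty
diagnostic; large datasets are trained chunk by chunk without weight
reinitialization (continual training).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from ._lstm import VLSTM, lstm_param_count

__all__ = [
    "TrainingConfig",
    "WindowedDataset",
    "TunedArchitecture",
    "minmax_fit",
    "minmax_apply",
    "minmax_invert",
    "make_windows",
    "build_model",
    "weighted_layer_loss",
    "tune_cells",
    "tune_layers",
    "train_chunked",
    "scaled_down_replication",
    "forecast",
    "evaluate",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainingConfig:
    """Training protocol defaults of the forecaster."""

    k: int = 6
    nt: int = 288  # history window, 5-min steps (24 h)
    pl: int = 288  # prediction length, 5-min steps (24 h)
    layers: int = 10
    cells: int = 64
    lr_initial: float = 1e-4
    lr_min: float = 1e-10
    lr_factor: float = 0.25
    lr_patience: int = 1
    early_stop_patience: int = 5
    early_stop_min_delta: float = 1e-5
    batch: int = 32
    max_epochs: int = 100
    val_split: float = 0.2
    test_split: float = 0.2

    def __post_init__(self) -> None:
        if not 0 < self.lr_factor < 1:
            raise ValueError("lr_factor must lie in (0, 1)")
        if self.lr_min >= self.lr_initial:
            raise ValueError("lr_min must be below lr_initial")
        for name in ("val_split", "test_split"):
            if not 0 < getattr(self, name) < 1:
                raise ValueError(f"{name} must lie in (0, 1)")


# ---------------------------------------------------------------------------
# normalization


def minmax_fit(curves) -> np.ndarray:
    """Per-attribute (min, max) bounds, shape (k, 2), over the curves.

    Constant attributes get their upper bound widened by 1e-9 so the
    map stays invertible.
    """
    mats = [np.asarray(_curve_matrix(c), dtype=float) for c in curves]
    stacked = np.concatenate(mats, axis=0)
    lo = stacked.min(axis=0)
    hi = stacked.max(axis=0)
    flat = hi <= lo
    if flat.any():
        warnings.warn("constant attribute(s); widening min-max bounds by 1e-9")
        hi = np.where(flat, lo + 1e-9, hi)
    return np.stack([lo, hi], axis=1)


def minmax_apply(values, bounds) -> np.ndarray:
    """Map raw values onto [0, 1] using fitted bounds (no clipping)."""
    values = np.asarray(values, dtype=float)
    bounds = np.asarray(bounds, dtype=float)
    if values.shape[-1] != bounds.shape[0]:
        raise ValueError(
            f"attribute count mismatch: values have {values.shape[-1]}, "
            f"bounds have {bounds.shape[0]}"
        )
    lo, hi = bounds[:, 0], bounds[:, 1]
    return (values - lo) / (hi - lo)


def minmax_invert(normalized, bounds) -> np.ndarray:
    """Inverse of :func:`minmax_apply` (exact round trip)."""
    normalized = np.asarray(normalized, dtype=float)
    bounds = np.asarray(bounds, dtype=float)
    if normalized.shape[-1] != bounds.shape[0]:
        raise ValueError("attribute count mismatch")
    lo, hi = bounds[:, 0], bounds[:, 1]
    return normalized * (hi - lo) + lo


def _curve_matrix(curve) -> np.ndarray:
    """(T, k) attribute matrix from a FermentationCurve or plain array."""
    if hasattr(curve, "data") and hasattr(curve.data, "to_numpy"):
        return curve.data.to_numpy(dtype=float)
    return np.asarray(curve, dtype=float)


# ---------------------------------------------------------------------------
# windowing


@dataclass
class WindowedDataset:
    """Normalized sliding-window inputs paired with forecast labels."""

    inputs: np.ndarray  # (N, nt, k)
    labels: np.ndarray  # (N, pl, k)
    norm_bounds: np.ndarray  # (k, 2)
    source_curve_ids: np.ndarray  # (N,) provenance labels

    def __post_init__(self) -> None:
        if len(self.inputs) != len(self.labels):
            raise ValueError("inputs and labels must align 1:1")

    def __len__(self) -> int:
        return len(self.inputs)

    def subset(self, idx) -> "WindowedDataset":
        return WindowedDataset(
            self.inputs[idx], self.labels[idx], self.norm_bounds, self.source_curve_ids[idx]
        )

    def split(self, fraction: float, seed: int = 0):
        """(rest, held_out) random split keeping provenance labels."""
        rng = np.random.default_rng(seed)
        n_held = max(1, int(round(len(self) * fraction)))
        perm = rng.permutation(len(self))
        return self.subset(np.sort(perm[n_held:])), self.subset(np.sort(perm[:n_held]))


def window_count(T: int, nt: int, pl: int, stride: int) -> int:
    """Number of (input, label) windows a length-T curve yields."""
    if T < nt + pl:
        return 0
    return (T - nt - pl) // stride + 1


def make_windows(curves, nt: int, pl: int, stride: int = 1, bounds=None) -> WindowedDataset:
    """Slide (nt input, pl label) windows over each curve at the stride.

    Curves shorter than nt + pl are skipped with a warning.  Bounds are
    fitted on the given curves unless supplied (supply training-set
    bounds when windowing held-out data).
    """
    if stride < 1 or nt < 1 or pl < 1:
        raise ValueError("nt, pl and stride must be ≥ 1")
    curves = list(curves)
    if bounds is None:
        bounds = minmax_fit(curves)
    inputs, labels, ids = [], [], []
    for ci, curve in enumerate(curves):
        mat = minmax_apply(_curve_matrix(curve), bounds)
        T = len(mat)
        n_win = window_count(T, nt, pl, stride)
        if n_win == 0:
            warnings.warn(f"curve {ci} ({T} samples) shorter than nt+pl={nt + pl}; skipped")
            continue
        for w in range(n_win):
            start = w * stride
            inputs.append(mat[start : start + nt])
            labels.append(mat[start + nt : start + nt + pl])
            ids.append(ci)
    if not inputs:
        return WindowedDataset(
            np.empty((0, nt, len(bounds))),
            np.empty((0, pl, len(bounds))),
            np.asarray(bounds),
            np.empty(0, dtype=int),
        )
    return WindowedDataset(
        np.stack(inputs).astype(np.float32),
        np.stack(labels).astype(np.float32),
        np.asarray(bounds, dtype=float),
        np.asarray(ids),
    )


# ---------------------------------------------------------------------------
# architecture


def build_model(
    nc: int, l: int, nt: int, pl: int, k: int, seed: int = 0, batch_norm: bool = True
) -> VLSTM:
    """Build the stacked-LSTM forecaster (see :class:`VLSTM`)."""
    return VLSTM(cells=nc, layers=l, nt=nt, pl=pl, k=k, seed=seed, batch_norm=batch_norm)


def weighted_layer_loss(rmse_per_layer, layers) -> np.ndarray:
    """Layer-count penalty: min-max-normalized RMSE × normalized depth.

    Zero at the minimum-RMSE candidate and at the shallowest candidate;
    bounded in [0, 1].  A constant RMSE list yields all zeros with a
    warning (the normalization is degenerate).
    """
    r = np.asarray(rmse_per_layer, dtype=float)
    ls = np.asarray(layers, dtype=float)
    if r.shape != ls.shape or r.size < 2:
        raise ValueError("need equal-length lists of at least 2 candidates")
    r_span = r.max() - r.min()
    l_span = ls.max() - ls.min()
    if r_span == 0 or l_span == 0:
        warnings.warn("degenerate min-max span in layer penalty; returning zeros")
        return np.zeros_like(r)
    return (r - r.min()) / r_span * (ls - ls.min()) / l_span


@dataclass
class TunedArchitecture:
    """Outcome of the two-stage width/depth search with full traces."""

    best_cells: int
    best_layers: int = 0
    cell_trace: list = field(default_factory=list)  # (candidate, val RMSE)
    layer_trace: list = field(default_factory=list)  # (candidate, val RMSE, penalty)


def _sample_cell_candidates(rng, low, high, trials, min_spacing):
    if (high - low) // min_spacing + 1 < trials:
        raise ValueError("cell range cannot hold the requested trials at this spacing")
    slots = np.arange(low, high + 1, min_spacing)
    picks = rng.choice(len(slots), size=trials, replace=False)
    return np.sort(slots[picks])


def _tuning_rmse(model, val_x, val_y, bounds, raw_scale):
    loss = model.evaluate_loss(val_x, val_y)
    if not raw_scale:
        return loss
    pred = np.concatenate(
        [model.forward(val_x[i : i + 64], training=False) for i in range(0, len(val_x), 64)]
    )
    resid = minmax_invert(pred, bounds) - minmax_invert(val_y, bounds)
    return float(np.sqrt(np.mean(resid**2)))


def tune_cells(
    dataset: WindowedDataset,
    seed: int = 0,
    cell_range: tuple = (32, 512),
    trials: int = 10,
    min_spacing: int = 32,
    epochs: int = 10,
    batch: int = 32,
    lr: float = 1e-4,
    val_split: float = 0.2,
    fraction: float = 1.0,
    raw_scale: bool = False,
) -> TunedArchitecture:
    """Stage 1: random search over cells/layer on a 1-layer model.

    Samples ``trials`` unique candidates at least ``min_spacing`` apart
    in ``cell_range``, trains each briefly, and keeps the candidate with
    the lowest validation RMSE (ties favour fewer cells).  ``fraction``
    restricts the search to a leading portion of the dataset (the
    protocol uses 1/12 of the full corpus).
    """
    rng = np.random.default_rng(seed)
    candidates = _sample_cell_candidates(rng, cell_range[0], cell_range[1], trials, min_spacing)
    ds = dataset if fraction >= 1.0 else dataset.subset(
        np.arange(max(2, int(len(dataset) * fraction)))
    )
    train, val = ds.split(val_split, seed=seed)
    nt, k = ds.inputs.shape[1], ds.inputs.shape[2]
    pl = ds.labels.shape[1]
    trace = []
    for nc in candidates:
        model = build_model(int(nc), 1, nt, pl, k, seed=seed)
        model.fit(
            train.inputs,
            train.labels,
            epochs=epochs,
            batch_size=batch,
            lr=lr,
            validation_data=(val.inputs, val.labels),
            seed=seed,
        )
        loss = _tuning_rmse(model, val.inputs, val.labels, ds.norm_bounds, raw_scale)
        trace.append((int(nc), float(loss)))
        logger.info("cells=%d val RMSE %.5f", nc, loss)
    best_cells = min(trace, key=lambda t: (t[1], t[0]))[0]
    return TunedArchitecture(best_cells=best_cells, cell_trace=trace)


def tune_layers(
    dataset: WindowedDataset,
    best_cells: int,
    seed: int = 0,
    layer_range: tuple = (1, 10),
    epochs: int = 10,
    batch: int = 32,
    lr: float = 1e-4,
    val_split: float = 0.2,
    fraction: float = 1.0,
    raw_scale: bool = False,
    select_by_penalty: bool = False,
) -> TunedArchitecture:
    """Stage 2: depth search at the fixed best width.

    Evaluates every depth in ``layer_range``, reports the layer-count
    penalty for each as a diagnostic, and selects the minimum-RMSE depth
    (or minimum-penalty depth when ``select_by_penalty``); ties favour
    fewer layers.
    """
    ds = dataset if fraction >= 1.0 else dataset.subset(
        np.arange(max(2, int(len(dataset) * fraction)))
    )
    train, val = ds.split(val_split, seed=seed)
    nt, k = ds.inputs.shape[1], ds.inputs.shape[2]
    pl = ds.labels.shape[1]
    candidates = list(range(layer_range[0], layer_range[1] + 1))
    rmses = []
    for l in candidates:
        model = build_model(best_cells, l, nt, pl, k, seed=seed)
        model.fit(
            train.inputs,
            train.labels,
            epochs=epochs,
            batch_size=batch,
            lr=lr,
            validation_data=(val.inputs, val.labels),
            seed=seed,
        )
        loss = _tuning_rmse(model, val.inputs, val.labels, ds.norm_bounds, raw_scale)
        rmses.append(float(loss))
        logger.info("layers=%d val RMSE %.5f", l, loss)
    penalties = weighted_layer_loss(rmses, candidates)
    trace = list(zip(candidates, rmses, penalties.tolist()))
    key = (lambda t: (t[2], t[0])) if select_by_penalty else (lambda t: (t[1], t[0]))
    best_layers = min(trace, key=key)[0]
    return TunedArchitecture(
        best_cells=best_cells, best_layers=best_layers, layer_trace=trace
    )


# ---------------------------------------------------------------------------
# training / inference


def train_chunked(
    model: VLSTM,
    chunks,
    config: TrainingConfig = TrainingConfig(),
    seed: int = 0,
    epochs: int | None = None,
) -> list:
    """Continual training over ordered dataset chunks.

    Weights carry over from chunk to chunk (no reinitialization); each
    chunk trains with its own validation split, early stopping and
    plateau learning-rate schedule.  Returns per-chunk history dicts.
    """
    histories = []
    for ci, chunk in enumerate(chunks):
        if len(chunk) == 0:
            warnings.warn(f"chunk {ci} is empty; skipped")
            continue
        hist = model.fit(
            chunk.inputs,
            chunk.labels,
            epochs=epochs if epochs is not None else config.max_epochs,
            batch_size=config.batch,
            lr=config.lr_initial,
            lr_factor=config.lr_factor,
            lr_patience=config.lr_patience,
            lr_min=config.lr_min,
            early_stop_patience=config.early_stop_patience,
            early_stop_min_delta=config.early_stop_min_delta,
            validation_split=config.val_split,
            seed=seed + ci,
        )
        histories.append({"chunk": ci, **hist})
        logger.info(
            "chunk %d: %d epochs, best val RMSE %.5f",
            ci,
            hist["epochs_ran"],
            hist["best_val_loss"],
        )
    return histories


def scaled_down_replication(
    seed: int = 0,
    n_fermentations: int = 10,
    stride: int = 48,
    cells: int = 64,
    layers: int = 2,
    epochs: int = 15,
    config: TrainingConfig = TrainingConfig(),
) -> dict:
    """Reduced-scale end-to-end forecasting study on synthetic data.

    Generates seeded 21-day fermentations, windows them with
    nt = pl = 288 at the given stride, holds out 20 % of the windows,
    trains a reduced forecaster (no output batch normalization — see the
    methods note) with Adam at the protocol learning rate, early
    stopping and the plateau schedule, and reports the mean held-out
    window RMSE on the normalized scale.
    """
    from .simulator import generate_dataset  # deferred: avoids cycle at import

    curves = generate_dataset(n_fermentations, seed=seed)
    dataset = make_windows(curves, nt=config.nt, pl=config.pl, stride=stride)
    rest, test = dataset.split(config.test_split, seed=seed)
    model = build_model(
        cells, layers, config.nt, config.pl, config.k, seed=seed, batch_norm=False
    )
    history = model.fit(
        rest.inputs,
        rest.labels,
        epochs=epochs,
        batch_size=config.batch,
        lr=config.lr_initial,
        lr_factor=config.lr_factor,
        lr_patience=config.lr_patience,
        lr_min=config.lr_min,
        early_stop_patience=config.early_stop_patience,
        early_stop_min_delta=config.early_stop_min_delta,
        validation_split=config.val_split,
        seed=seed,
    )
    test_rmse = evaluate(model, test)
    baseline = float(
        np.sqrt(np.mean((test.labels - rest.labels.mean(axis=(0, 1))) ** 2))
    )
    return {
        "test_rmse": test_rmse,
        "mean_baseline_rmse": baseline,
        "n_windows": len(dataset),
        "n_test_windows": len(test),
        "epochs_ran": history["epochs_ran"],
        "best_val_rmse": history["best_val_loss"],
        "model": model,
        "dataset": dataset,
    }


def forecast(model: VLSTM, window, bounds) -> np.ndarray:
    """Predict the next pl raw-unit samples from one raw (nt, k) window."""
    window = np.asarray(window, dtype=float)
    if window.shape != (model.nt, model.k):
        raise ValueError(f"window must have shape ({model.nt}, {model.k})")
    normalized = minmax_apply(window, bounds)
    pred = model.forward(normalized[None, :, :], training=False)[0]
    return minmax_invert(pred, bounds)


def evaluate(model: VLSTM, test: WindowedDataset, batch_size: int = 64) -> float:
    """Mean per-window RMSE on the normalized scale over held-out windows."""
    if len(test) == 0:
        raise ValueError("cannot evaluate on an empty test set")
    rmses = []
    for start in range(0, len(test), batch_size):
        pred = model.forward(test.inputs[start : start + batch_size], training=False)
        resid = pred.astype(np.float64) - test.labels[start : start + batch_size]
        rmses.extend(np.sqrt(np.mean(resid**2, axis=(1, 2))))
    return float(np.mean(rmses))
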