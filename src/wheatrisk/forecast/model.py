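"""One-step-ahead pyramid-attention forecasting of weekly risk indicators.

One model is fitted per (province, indicator) series.  The architecture
follows the sparse pyramid-attention design for time series:

* **Input embedding** — the standardized observation, a learned week-of-year
  embedding (the seasonal covariate, on a fixed 52-week year) and a fixed
  sinusoidal positional encoding are summed elementwise.
* **CSCM (coarse-scale construction)** — coarser scales are initialized by
  strided aggregation: each coarse node averages its C consecutive children
  (the last node may own fewer) and applies a learned projection with a ReLU.
* **PAM (pyramid attention)** — multi-head attention over all nodes of all
  scales, masked so that each query attends only to itself, its intra-scale
  neighbors within radius A, its C children and its parent.  The coarsest
  scale plays the role of the global summary tokens.
* **Prediction head** — the final node of every scale is gathered,
  concatenated and mapped by an affine layer to the next standardized value,
  then de-standardized.

Training minimizes mean squared error with Adam on all (window, next value)
pairs of the training span; inference is teacher-forced one-step prediction
(each test week conditions on the actually observed history).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from ..synthetic import week_of_year
from .autodiff import Adam, Tensor

WEEKS_PER_YEAR = 52


@dataclass(frozen=True)
class PyramidConfig:
    """Hyperparameters of the pyramid-attention forecaster."""

    window: int = 24  # T, input sequence length
    children: int = 4  # C, children per parent node
    scales: int = 3  # S, number of scales including the finest
    neighbor_radius: int = 1  # A, intra-scale attention radius
    width: int = 32  # model (embedding) dimension
    heads: int = 4
    epochs: int = 200
    learning_rate: float = 1e-3
    batch_size: int = 16
    # sd of seeded Gaussian noise added to the standardized observations of
    # each training batch; discourages memorizing one year's exact history and
    # pushes the model onto the recurring week-of-year covariate
    input_noise: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.children < 2:
            raise ValueError("children per parent (C) must be >= 2")
        if self.scales < 2:
            raise ValueError("number of scales (S) must be >= 2")
        if self.window < self.children ** (self.scales - 1):
            raise ValueError("window T must be >= C**(S-1) so every scale is nonempty")
        if self.width % self.heads != 0:
            raise ValueError("width must be divisible by heads")


@dataclass(frozen=True)
class PyramidGraph:
    """Node layout and attention adjacency of the pyramid."""

    node_counts: tuple[int, ...]  # per-scale node counts, finest first
    mask: np.ndarray  # (N, N) boolean; mask[q, k] = query q may attend key k
    scale_offsets: tuple[int, ...]  # start index of each scale in the flat layout

    @property
    def total_nodes(self) -> int:
        return int(sum(self.node_counts))

    @property
    def last_node_indices(self) -> tuple[int, ...]:
        """Flat index of the final node of every scale (the prediction taps)."""
        return tuple(
            offset + count - 1 for offset, count in zip(self.scale_offsets, self.node_counts)
        )


def build_pyramid_graph(config: PyramidConfig) -> PyramidGraph:
    """Construct node counts (repeated ceil division by C) and the attention mask.

    Allowed keys of a node: itself and intra-scale neighbors within radius A,
    its children at the next finer scale, and its parent at the next coarser
    scale.  Parent/child adjacency is symmetric by construction; the last
    parent of a scale may own fewer than C children when the finer count is
    not divisible by C.
    """
    t, c, s, a = config.window, config.children, config.scales, config.neighbor_radius
    counts = [t]
    for _ in range(s - 1):
        counts.append(-(-counts[-1] // c))  # ceil division
    offsets = tuple(int(x) for x in np.concatenate([[0], np.cumsum(counts)[:-1]]))
    n = int(sum(counts))
    mask = np.zeros((n, n), dtype=bool)
    for scale, count in enumerate(counts):
        base = offsets[scale]
        for i in range(count):
            q = base + i
            lo, hi = max(0, i - a), min(count - 1, i + a)
            mask[q, base + lo : base + hi + 1] = True  # intra-scale incl. self
            if scale + 1 < s:  # parent
                mask[q, offsets[scale + 1] + i // c] = True
            if scale > 0:  # children
                child_base = offsets[scale - 1]
                child_lo = i * c
                child_hi = min(counts[scale - 1], (i + 1) * c)
                mask[q, child_base + child_lo : child_base + child_hi] = True
    return PyramidGraph(tuple(counts), mask, offsets)


def _positional_encoding(length: int, width: int) -> np.ndarray:
    position = np.arange(length)[:, None]
    div = np.exp(np.arange(0, width, 2) * (-np.log(10000.0) / width))
    pe = np.zeros((length, width))
    pe[:, 0::2] = np.sin(position * div)
    pe[:, 1::2] = np.cos(position * div[: pe[:, 1::2].shape[1]])
    return pe


def _block_mean_matrix(n_coarse: int, n_fine: int, c: int) -> np.ndarray:
    """(n_coarse, n_fine) constant matrix averaging C consecutive fine nodes."""
    m = np.zeros((n_coarse, n_fine))
    for i in range(n_coarse):
        lo, hi = i * c, min((i + 1) * c, n_fine)
        m[i, lo:hi] = 1.0 / (hi - lo)
    return m


class PyramidAttentionModel:
    """Parameter container and forward pass; used through :func:`fit_forecaster`."""

    def __init__(self, config: PyramidConfig):
        self.config = config
        self.graph = build_pyramid_graph(config)
        d = config.width
        rng = np.random.default_rng(config.seed)

        def param(*shape: int, scale: float | None = None) -> Tensor:
            scale = scale if scale is not None else 1.0 / np.sqrt(shape[0])
            return Tensor(rng.normal(0.0, scale, size=shape), requires_grad=True)

        self.value_w = param(1, d, scale=1.0)
        self.value_b = Tensor(np.zeros(d), requires_grad=True)
        # seasonal covariate embedding, initialized at the same scale as the
        # observation embedding so week-of-year structure is salient from the
        # first epochs (rows 1..52 used)
        self.week_emb = param(WEEKS_PER_YEAR + 1, d, scale=1.0)
        self.pe = _positional_encoding(config.window, d)
        # CSCM: one projection per coarse scale
        self.cscm_w = [param(d, d) for _ in range(config.scales - 1)]
        self.cscm_b = [Tensor(np.zeros(d), requires_grad=True) for _ in range(config.scales - 1)]
        self._block_mats = []
        counts = self.graph.node_counts
        for s in range(1, config.scales):
            self._block_mats.append(
                Tensor(_block_mean_matrix(counts[s], counts[s - 1], config.children))
            )
        # PAM: multi-head attention + feed-forward
        self.wq, self.wk, self.wv, self.wo = (param(d, d) for _ in range(4))
        self.ff1_w, self.ff1_b = param(d, 2 * d), Tensor(np.zeros(2 * d), requires_grad=True)
        self.ff2_w, self.ff2_b = param(2 * d, d), Tensor(np.zeros(d), requires_grad=True)
        # head over the concatenated last node of every scale
        self.head_w = param(config.scales * d, 1)
        self.head_b = Tensor(np.zeros(1), requires_grad=True)

    @property
    def parameters(self) -> list[Tensor]:
        return (
            [self.value_w, self.value_b, self.week_emb]
            + self.cscm_w
            + self.cscm_b
            + [self.wq, self.wk, self.wv, self.wo,
               self.ff1_w, self.ff1_b, self.ff2_w, self.ff2_b,
               self.head_w, self.head_b]
        )

    # -- forward stages ----------------------------------------------------
    def embed_inputs(self, values: np.ndarray, weeks: np.ndarray) -> Tensor:
        """Sum of observation embedding, week-of-year embedding and positional
        encoding; ``values`` is (batch, T) standardized, ``weeks`` is (batch, T)
        integer weeks-of-year in 1..52."""
        b, t = values.shape
        v = Tensor(values.reshape(b, t, 1))
        obs = v @ self.value_w + self.value_b
        week = self.week_emb.gather(weeks.astype(int), axis=0)  # (b, t, d)
        return obs + week + Tensor(self.pe)

    def cscm_forward(self, embedded: Tensor) -> list[Tensor]:
        """Features for every scale; coarse nodes aggregate C consecutive finer
        nodes by averaging followed by a learned projection."""
        features = [embedded]
        for mat, w, b in zip(self._block_mats, self.cscm_w, self.cscm_b):
            pooled = mat @ features[-1]  # (b, n_coarse, d)
            features.append((pooled @ w + b).relu())
        return features

    def pam_forward(self, nodes: Tensor) -> Tensor:
        """One block of mask-restricted multi-head attention plus feed-forward."""
        cfg = self.config
        b, n, d = nodes.shape
        h, dh = cfg.heads, d // cfg.heads

        def split(x: Tensor) -> Tensor:
            return x.reshape(b, n, h, dh).transpose(0, 2, 1, 3)  # (b, h, n, dh)

        q, k, v = split(nodes @ self.wq), split(nodes @ self.wk), split(nodes @ self.wv)
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dh))
        weights = scores.masked_softmax(self.graph.mask, axis=-1)
        attended = (weights @ v).transpose(0, 2, 1, 3).reshape(b, n, d) @ self.wo
        x = (nodes + attended).layer_norm()
        ff = ((x @ self.ff1_w + self.ff1_b).relu() @ self.ff2_w + self.ff2_b)
        return (x + ff).layer_norm()

    def forward(self, values: np.ndarray, weeks: np.ndarray) -> Tensor:
        """Standardized one-step prediction, shape (batch,)."""
        embedded = self.embed_inputs(values, weeks)
        features = self.cscm_forward(embedded)
        nodes = Tensor.concat(features, axis=1)
        contextual = self.pam_forward(nodes)
        taps = contextual.gather(np.array(self.graph.last_node_indices), axis=1)
        b = values.shape[0]
        flat = taps.reshape(b, self.config.scales * self.config.width)
        return (flat @ self.head_w + self.head_b).reshape(b)

    # -- (de)serialization ---------------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        names = self._param_names()
        return {name: p.data for name, p in zip(names, self.parameters)}

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        for name, p in zip(self._param_names(), self.parameters):
            p.data = np.asarray(arrays[name], dtype=np.float64)

    def _param_names(self) -> list[str]:
        n_coarse = self.config.scales - 1
        return (
            ["value_w", "value_b", "week_emb"]
            + [f"cscm_w{i}" for i in range(n_coarse)]
            + [f"cscm_b{i}" for i in range(n_coarse)]
            + ["wq", "wk", "wv", "wo", "ff1_w", "ff1_b", "ff2_w", "ff2_b", "head_w", "head_b"]
        )


@dataclass
class TrainedForecaster:
    """A fitted pyramid-attention model for one indicator series."""

    model: PyramidAttentionModel
    config: PyramidConfig
    mean: float  # training-span standardization constants
    scale: float
    loss_trace: list[float] = field(default_factory=list)

    def predict_next(self, observations: np.ndarray, weeks: np.ndarray) -> float:
        """Predict the value following a window of T observed values.

        ``observations`` are raw (unstandardized) indicator values of length
        T; ``weeks`` the matching week-of-year covariates.  Deterministic
        given the fitted parameters.
        """
        observations = np.asarray(observations, dtype=float)
        weeks = np.asarray(weeks)
        t = self.config.window
        if observations.shape != (t,) or weeks.shape != (t,):
            raise ValueError(f"predict_next expects a window of length T={t}")
        std = (observations - self.mean) / self.scale
        pred = self.model.forward(std[None, :], weeks[None, :])
        return float(pred.data[0] * self.scale + self.mean)


def make_windows(
    series: np.ndarray, weeks: np.ndarray, window: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All (window, target) pairs: returns (values (n, T), weeks (n, T), targets (n,))."""
    n = len(series) - window
    if n < 1:
        raise ValueError(f"series of length {len(series)} too short for window T={window}")
    values = np.stack([series[i : i + window] for i in range(n)])
    wk = np.stack([weeks[i : i + window] for i in range(n)])
    targets = series[window:]
    return values, wk, targets


def fit_forecaster(
    series: np.ndarray, weeks: np.ndarray, config: PyramidConfig
) -> TrainedForecaster:
    """Fit the model on every (window, next value) pair of ``series``.

    The series is standardized with its own mean and standard deviation
    (a degenerate constant series falls back to unit scale); training is
    mini-batch Adam on mean squared error, deterministic given the config
    seed.  Returns the model with its per-epoch loss trace.
    """
    series = np.asarray(series, dtype=float)
    weeks = np.asarray(weeks)
    if len(series) <= config.window:
        raise ValueError(
            f"series length {len(series)} must exceed the window T={config.window}"
        )
    mean = float(series.mean())
    scale = float(series.std())
    if scale == 0.0 or not np.isfinite(scale):
        scale = 1.0
    std_series = (series - mean) / scale

    values, wk, targets = make_windows(std_series, weeks, config.window)
    model = PyramidAttentionModel(config)
    optimizer = Adam(model.parameters, lr=config.learning_rate)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(17,)))
    n = len(targets)
    loss_trace: list[float] = []
    for _ in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            batch_values = values[idx]
            if config.input_noise > 0:
                batch_values = batch_values + config.input_noise * rng.standard_normal(
                    batch_values.shape
                )
            pred = model.forward(batch_values, wk[idx])
            err = pred - Tensor(targets[idx])
            loss = (err * err).mean()
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            epoch_loss += float(loss.data) * len(idx)
        loss_trace.append(epoch_loss / n)
    return TrainedForecaster(model=model, config=config, mean=mean, scale=scale,
                             loss_trace=loss_trace)


def build_series(
    indicators: pd.DataFrame, province: str, indicator: str
) -> tuple[np.ndarray, np.ndarray]:
    """Ordered indicator series and week-of-year covariates for one province.

    Requires contiguous global weeks; gaps raise with the missing weeks listed.
    """
    sub = indicators[indicators["province"] == province].sort_values("week")
    if sub.empty:
        raise ValueError(f"no rows for province {province!r}")
    if indicator not in sub.columns:
        raise ValueError(f"unknown indicator {indicator!r}")
    weeks = sub["week"].to_numpy()
    expected = np.arange(weeks[0], weeks[-1] + 1)
    if len(weeks) != len(expected) or (weeks != expected).any():
        missing = sorted(int(w) for w in set(expected) - set(weeks))
        raise ValueError(f"weeks not contiguous for {province}: missing {missing}")
    return sub[indicator].to_numpy(dtype=float), np.asarray(week_of_year(weeks))


def save_forecaster(forecaster: TrainedForecaster, directory: str | Path, name: str) -> None:
    """Write parameter arrays (.npz) plus a JSON sidecar with config and constants."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.savez(directory / f"{name}.npz", **forecaster.model.state_arrays())
    sidecar = {
        "config": asdict(forecaster.config),
        "mean": forecaster.mean,
        "scale": forecaster.scale,
        "loss_trace": forecaster.loss_trace,
    }
    (directory / f"{name}.json").write_text(json.dumps(sidecar))


def load_forecaster(directory: str | Path, name: str) -> TrainedForecaster:
    directory = Path(directory)
    sidecar = json.loads((directory / f"{name}.json").read_text())
    config = PyramidConfig(**sidecar["config"])
    model = PyramidAttentionModel(config)
    with np.load(directory / f"{name}.npz") as arrays:
        model.load_state_arrays(dict(arrays))
    return TrainedForecaster(
        model=model,
        config=config,
        mean=float(sidecar["mean"]),
        scale=float(sidecar["scale"]),
        loss_trace=list(sidecar["loss_trace"]),
    )


__all__ = [
    "PyramidAttentionModel",
    "PyramidConfig",
    "PyramidGraph",
    "TrainedForecaster",
    "build_pyramid_graph",
    "build_series",
    "fit_forecaster",
    "load_forecaster",
    "make_windows",
    "save_forecaster",
]
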