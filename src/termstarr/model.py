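"""Strength prediction models and greedy in-silico evolution.

Two sequence-to-strength regressors are provided:

* a 6-mer L1-penalized linear model (one coefficient per 4^6 = 4,096 k-mer,
  per assay system), fit on a 70/30 train/test split with the penalty chosen
  by cross-validation on the training split;
* a densely connected convolutional network over one-hot DNA: an initial
  convolution (128 filters, kernel 5) followed by four dense blocks of
  6/12/24/16 composite layers (12 filters each, kernel 3) in which every
  layer's output is concatenated onto its input, transitions that halve the
  channel count (kernel-1 convolution) and average-pool by 2, and a fully
  connected head with two outputs (tobacco leaves, maize protoplasts).

Either model can drive greedy in-silico evolution: each round scores every
single-nucleotide substitution variant of the incumbent sequence and keeps
the variant with the highest predicted strength under the chosen objective.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import nn
from .features import count_kmers, kmer_universe
from .seqlib import BASES, TERMINATOR_LENGTH

SYSTEMS = ("tobacco", "maize")

_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


def one_hot(sequences: Sequence[str], length: int = TERMINATOR_LENGTH) -> np.ndarray:
    """(N, 4, L) one-hot encoding; rejects wrong lengths and non-ACGT bases."""
    n = len(sequences)
    out = np.zeros((n, 4, length), dtype=nn.DTYPE)
    for i, s in enumerate(sequences):
        if len(s) != length:
            raise ValueError(f"sequence {i} has length {len(s)}, expected {length}")
        for j, b in enumerate(s):
            try:
                out[i, _BASE_INDEX[b], j] = 1.0
            except KeyError:
                raise ValueError(f"sequence {i}: invalid base {b!r}") from None
    return out


def r_squared(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    ss_res = ((y_true - y_pred) ** 2).sum()
    ss_tot = ((y_true - y_true.mean()) ** 2).sum()
    return float(1.0 - ss_res / ss_tot)


# ---------------------------------------------------------------------------
# 6-mer lasso
# ---------------------------------------------------------------------------

@dataclass
class KmerLassoModel:
    k: int
    coefficients: dict[str, np.ndarray]   # system -> 4^k vector
    intercepts: dict[str, float]
    penalties: dict[str, float]
    split_seed: int
    heldout_r2: dict[str, float]

    def predict(self, sequences: Sequence[str]) -> np.ndarray:
        X = count_kmers(sequences, k=self.k).counts.astype(float)
        return np.stack(
            [X @ self.coefficients[s] + self.intercepts[s] for s in SYSTEMS],
            axis=1,
        )

    def coefficient_frame(self, system: str) -> pd.DataFrame:
        return pd.DataFrame({"kmer": kmer_universe(self.k),
                             "coef": self.coefficients[system]})


def fit_kmer_lasso(sequences: Sequence[str], strengths: Mapping[str, Sequence[float]],
                   k: int = 6, split_seed: int = 0, train_fraction: float = 0.7,
                   cv: int = 5) -> KmerLassoModel:
    """Fit the per-system k-mer lasso on a 70/30 split.

    ``strengths`` maps system name to per-sequence responses (log2 strengths
    by convention).  The L1 penalty is chosen by ``cv``-fold cross-validation
    on the training split; held-out R^2 is reported on the remaining 30%.
    """
    from sklearn.linear_model import LassoCV

    if len(sequences) < 100:
        raise ValueError("need >= 100 training sequences")
    X = count_kmers(sequences, k=k).counts.astype(float)
    rng = np.random.default_rng(split_seed)
    order = rng.permutation(len(sequences))
    n_train = int(round(train_fraction * len(sequences)))
    train_idx, test_idx = order[:n_train], order[n_train:]

    coefs, intercepts, penalties, r2 = {}, {}, {}, {}
    for system, y in strengths.items():
        y = np.asarray(y, dtype=float)
        if np.allclose(y, y[0]):
            raise ValueError(f"{system}: constant response")
        las = LassoCV(cv=cv, random_state=split_seed, alphas=30, max_iter=5000)
        las.fit(X[train_idx], y[train_idx])
        coefs[system] = las.coef_.copy()
        intercepts[system] = float(las.intercept_)
        penalties[system] = float(las.alpha_)
        r2[system] = r_squared(y[test_idx], las.predict(X[test_idx]))
    return KmerLassoModel(k=k, coefficients=coefs, intercepts=intercepts,
                          penalties=penalties, split_seed=split_seed,
                          heldout_r2=r2)


# ---------------------------------------------------------------------------
# DenseNet
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DenseNetConfig:
    initial_filters: int = 128
    initial_kernel: int = 5
    block_layers: tuple[int, ...] = (6, 12, 24, 16)
    growth_filters: int = 12
    block_kernel: int = 3
    transition_pool: int = 2
    transition_filter_ratio: float = 0.5
    outputs: int = 2
    input_length: int = TERMINATOR_LENGTH
    #: head over the final feature map: "flatten" keeps position-specific
    #: weights; "gap" averages over positions before the linear readout
    head: str = "flatten"


def channel_schedule(cfg: DenseNetConfig) -> list[dict[str, int]]:
    """Channel/length bookkeeping per stage, from the concatenation formula.

    Each dense block adds ``n_layers * growth`` channels to its input; each
    transition multiplies channels by the filter ratio and divides the length
    by the pooling kernel.  Raises if the pooling arithmetic exhausts the
    feature map, naming the offending block.
    """
    stages = []
    c = cfg.initial_filters
    L = cfg.input_length
    for i, n_layers in enumerate(cfg.block_layers):
        c_after = c + n_layers * cfg.growth_filters
        stage = {"block": i + 1, "channels_in": c, "channels_after_block": c_after}
        if i < len(cfg.block_layers) - 1:
            c = int(c_after * cfg.transition_filter_ratio)
            L = L // cfg.transition_pool
            if L < 1:
                raise ValueError(f"feature map vanishes at transition after block {i + 1}")
            stage["channels_after_transition"] = c
            stage["length_after_transition"] = L
        else:
            stage["channels_after_transition"] = c_after
            stage["length_after_transition"] = L
            c = c_after
        stages.append(stage)
    return stages


class DenseNetModel:
    """Two-output DenseNet strength regressor over one-hot DNA."""

    def __init__(self, cfg: DenseNetConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        schedule = channel_schedule(cfg)  # validates arithmetic
        layers: list[nn.Layer] = [nn.Conv1d(4, cfg.initial_filters,
                                            cfg.initial_kernel, rng)]
        c, L = cfg.initial_filters, cfg.input_length
        for i, n_layers in enumerate(cfg.block_layers):
            layers.append(nn.DenseBlock(c, n_layers, cfg.growth_filters,
                                        cfg.block_kernel, rng))
            c += n_layers * cfg.growth_filters
            if i < len(cfg.block_layers) - 1:
                layers.extend([
                    nn.BatchNorm1d(c), nn.ReLU(),
                    nn.Conv1d(c, int(c * cfg.transition_filter_ratio), 1, rng),
                    nn.AvgPool1d(cfg.transition_pool),
                ])
                c = int(c * cfg.transition_filter_ratio)
                L = L // cfg.transition_pool
        if cfg.head == "gap":
            layers.extend([nn.BatchNorm1d(c), nn.ReLU(), nn.GlobalAvgPool(),
                           nn.Linear(c, cfg.outputs, rng)])
        elif cfg.head == "flatten":
            layers.extend([nn.BatchNorm1d(c), nn.ReLU(), nn.Flatten(),
                           nn.Linear(c * L, cfg.outputs, rng)])
        else:
            raise ValueError(f"unknown head {cfg.head!r}")
        self.net = nn.Sequential(layers)
        self.schedule = schedule
        # target standardization, identity until trained
        self.y_mean = np.zeros(cfg.outputs)
        self.y_std = np.ones(cfg.outputs)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.net.forward(x, train)

    def predict(self, sequences: Sequence[str], batch_size: int = 256) -> np.ndarray:
        """Deterministic inference; returns (N, outputs) scores."""
        X = one_hot(sequences, self.cfg.input_length)
        outs = []
        for i in range(0, len(X), batch_size):
            z = self.net.forward(X[i:i + batch_size], train=False)
            outs.append(z * self.y_std + self.y_mean)
        return np.concatenate(outs, axis=0)


def build_densenet(cfg: DenseNetConfig | None = None, seed: int = 0) -> DenseNetModel:
    return DenseNetModel(cfg or DenseNetConfig(), seed=seed)


@dataclass
class TrainResult:
    model: DenseNetModel
    test_r2: dict[str, float]
    history: list[tuple[int, float, float]]  # (epoch, train_mse, val_mse)
    split_indices: dict[str, np.ndarray]


def train_densenet(sequences: Sequence[str], targets: np.ndarray,
                   cfg: DenseNetConfig | None = None,
                   split: tuple[float, float, float] = (0.81, 0.09, 0.10),
                   seed: int = 0, lr: float = 1e-3, batch_size: int = 128,
                   max_epochs: int = 100, patience: int = 10,
                   verbose: bool = False) -> TrainResult:
    """Train the DenseNet on log2-strength targets.

    The data are split 81/9/10 into train/validation/test; training minimizes
    the mean squared error summed over the two outputs with Adam, stopping
    early when the validation loss has not improved for ``patience`` epochs
    and restoring the best weights.  Reports per-output test R^2.
    """
    targets = np.asarray(targets, dtype=float)
    if targets.ndim != 2:
        raise ValueError("targets must be (N, outputs)")
    if not np.isclose(sum(split), 1.0):
        raise ValueError("split fractions must sum to 1")
    cfg = cfg or DenseNetConfig()
    n = len(sequences)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = int(round(split[0] * n))
    n_val = int(round(split[1] * n))
    idx = {"train": order[:n_train], "val": order[n_train:n_train + n_val],
           "test": order[n_train + n_val:]}

    X = one_hot(sequences, cfg.input_length)
    model = DenseNetModel(cfg, seed=seed)
    model.y_mean = targets[idx["train"]].mean(axis=0)
    model.y_std = targets[idx["train"]].std(axis=0)
    model.y_std[model.y_std == 0] = 1.0
    Y = ((targets - model.y_mean) / model.y_std).astype(nn.DTYPE)

    opt = nn.Adam(model.net.params(), lr=lr)
    best_val = np.inf
    best_weights = nn.get_weights(model.net)
    best_epoch = 0
    history = []

    def mse_on(split_name: str) -> float:
        ii = idx[split_name]
        err = 0.0
        for i in range(0, len(ii), 512):
            b = ii[i:i + 512]
            z = model.net.forward(X[b], train=False)
            err += ((z - Y[b]) ** 2).sum()
        return err / len(ii)

    for epoch in range(1, max_epochs + 1):
        perm = rng.permutation(idx["train"])
        train_err = 0.0
        for i in range(0, len(perm), batch_size):
            b = perm[i:i + batch_size]
            z = model.net.forward(X[b], train=True)
            diff = z - Y[b]
            loss = (diff**2).sum()
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}; "
                    "reduce the learning rate")
            train_err += loss
            opt.zero_grad()
            model.net.backward((2.0 * diff / len(b)).astype(nn.DTYPE))
            opt.step()
        val_err = mse_on("val")
        history.append((epoch, train_err / len(perm), val_err))
        if verbose:
            print(f"epoch {epoch}: train {train_err / len(perm):.4f} val {val_err:.4f}")
        if val_err < best_val - 1e-6:
            best_val = val_err
            best_weights = nn.get_weights(model.net)
            best_epoch = epoch
        else:
            if epoch - best_epoch >= patience:
                break
            # halve the learning rate on a validation plateau
            if (epoch - best_epoch) % 4 == 0 and opt.lr > 1e-4:
                opt.lr *= 0.5
    nn.set_weights(model.net, best_weights)

    test_pred = model.predict([sequences[i] for i in idx["test"]])
    test_true = targets[idx["test"]]
    test_r2 = {
        system: r_squared(test_true[:, j], test_pred[:, j])
        for j, system in enumerate(SYSTEMS[: cfg.outputs])
    }
    return TrainResult(model=model, test_r2=test_r2, history=history,
                       split_indices=idx)


# ---------------------------------------------------------------------------
# in-silico evolution
# ---------------------------------------------------------------------------

@dataclass
class EvolutionStep:
    round: int
    sequence: str
    score_tobacco: float
    score_maize: float
    objective: float
    edited_position: int | None  # 1-based, None for round 0 / retained incumbent
    substituted_base: str | None


Scorer = Callable[[Sequence[str]], np.ndarray]


def as_scorer(model) -> Scorer:
    """Adapt a trained model (or a callable) to the batch scorer interface."""
    if callable(model) and not hasattr(model, "predict"):
        return model
    return model.predict


def _objective(scores: np.ndarray, objective: str) -> np.ndarray:
    if objective == "tobacco":
        return scores[:, 0]
    if objective == "maize":
        return scores[:, 1]
    if objective == "both":
        return scores[:, 0] + scores[:, 1]
    raise ValueError(f"invalid objective {objective!r}")


def evolve(start: str, scorer, objective: str = "both", rounds: int = 10,
           keep_current: bool = False) -> list[EvolutionStep]:
    """Greedy single-substitution hill climbing under a model score.

    Each round enumerates all 3L single-substitution variants of the
    incumbent, scores them in one batch, and selects the variant maximizing
    the objective (a single system's score, or the sum of both).  Ties break
    lexicographically by (position, base).  With ``keep_current`` the
    incumbent is retained when no variant beats it, making the objective
    non-decreasing.
    """
    if rounds < 0:
        raise ValueError("rounds must be >= 0")
    if set(start) - set(BASES):
        raise ValueError("start sequence must be over ACGT")
    score_fn = as_scorer(scorer)

    def score_one(seq: str) -> np.ndarray:
        return np.asarray(score_fn([seq]), dtype=float).reshape(1, -1)[0]

    s0 = score_one(start)
    trajectory = [EvolutionStep(0, start, float(s0[0]), float(s0[-1]),
                                float(_objective(s0[None, :], objective)[0]),
                                None, None)]
    current = start
    current_obj = trajectory[0].objective
    for r in range(1, rounds + 1):
        variants, edits = [], []
        for pos in range(len(current)):
            for b in BASES:
                if b != current[pos]:
                    variants.append(current[:pos] + b + current[pos + 1:])
                    edits.append((pos, b))
        scores = np.asarray(score_fn(variants), dtype=float).reshape(len(variants), -1)
        obj = _objective(scores, objective)
        best = int(np.argmax(obj))  # first occurrence wins: (position, base) order
        if keep_current and obj[best] <= current_obj:
            trajectory.append(EvolutionStep(r, current,
                                            trajectory[-1].score_tobacco,
                                            trajectory[-1].score_maize,
                                            current_obj, None, None))
            continue
        pos, b = edits[best]
        current = variants[best]
        current_obj = float(obj[best])
        trajectory.append(EvolutionStep(r, current, float(scores[best, 0]),
                                        float(scores[best, -1]), current_obj,
                                        pos + 1, b))
    return trajectory


def trajectory_frame(trajectory: Sequence[EvolutionStep]) -> pd.DataFrame:
    return pd.DataFrame([
        {"round": s.round, "sequence": s.sequence, "score_tobacco": s.score_tobacco,
         "score_maize": s.score_maize, "objective": s.objective,
         "edited_position": s.edited_position, "substituted_base": s.substituted_base}
        for s in trajectory
    ])


def ism_attribution(model, sequence: str, output: int = 0) -> np.ndarray:
    """In-silico mutagenesis attribution map.

    ``delta[p, b] = score(sequence with base b at position p) - score(sequence)``
    for the selected output; the reference base's delta is 0 by construction.
    Returns an (L, 4) matrix with columns in ACGT order.
    """
    score_fn = as_scorer(model)
    base_score = np.asarray(score_fn([sequence]), dtype=float).reshape(1, -1)[0, output]
    L = len(sequence)
    variants, coords = [], []
    for pos in range(L):
        for bi, b in enumerate(BASES):
            if b != sequence[pos]:
                variants.append(sequence[:pos] + b + sequence[pos + 1:])
                coords.append((pos, bi))
    scores = np.asarray(score_fn(variants), dtype=float).reshape(len(variants), -1)
    delta = np.zeros((L, 4))
    for (pos, bi), s in zip(coords, scores[:, output]):
        delta[pos, bi] = s - base_score
    return delta
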