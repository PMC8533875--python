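"""Shallow LSTM binary authenticator.

The feature matrix of an epoch is consumed as a sequence: each STFT frame is
one time step, each (channel, sub-band) row one input dimension.  The network
is a single LSTM layer whose final hidden state feeds a fully connected layer
with a two-unit softmax head over {No, Yes}; training minimizes cross-entropy
with the Adam optimizer.  Implemented in NumPy (forward pass and
backpropagation through time), which keeps a learner of this size fast on a
single CPU core and makes every run bit-reproducible under the config seed.

Inputs are z-scored per feature dimension using statistics computed on the
training set only.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .features import FeatureMatrix
from .synth import ValidationError

__all__ = ["LearnerConfig", "LabeledSet", "WeakLearner", "train_learner",
           "predict", "save_learner", "load_learner"]

_FORMAT_VERSION = 1


@dataclass(frozen=True)
class LearnerConfig:
    hidden_units: int = 64
    epochs: int = 60
    batch_size: int = 8
    learning_rate: float = 1e-3
    seed: int = 0
    decision_threshold: float = 0.5
    normalization: str = "zscore_train"  # "zscore_train" | "none"

    def validate(self) -> None:
        if min(self.hidden_units, self.epochs, self.batch_size) <= 0:
            raise ValidationError("counts must be positive")
        if self.learning_rate <= 0:
            raise ValidationError("learning_rate must be positive")
        if not 0.0 < self.decision_threshold < 1.0:
            raise ValidationError("decision_threshold must lie in (0, 1)")
        if self.normalization not in ("zscore_train", "none"):
            raise ValidationError(
                f"unknown normalization '{self.normalization}'")


#: Compact training profile for cohort-scale evaluations: a small hidden
#: layer trained full-batch with a higher learning rate separates the
#: sub-band fingerprints just as well as the default profile at a fraction
#: of the cost (see docs/methods.md).
COMPACT_PROFILE_KWARGS = dict(hidden_units=16, epochs=25, batch_size=64,
                              learning_rate=1e-2)


@dataclass
class LabeledSet:
    """Feature matrices with {0: imposter/No, 1: authorized/Yes} labels.

    ``provenance`` optionally records (subject_id, day_index) per example so
    evaluation can assert train/test disjointness.
    """

    features: list  # of FeatureMatrix
    labels: np.ndarray
    provenance: list = field(default_factory=list)

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.features) != self.labels.size:
            raise ValidationError("features and labels lengths differ")

    def __len__(self) -> int:
        return len(self.features)

    def validate_for_training(self) -> None:
        if len(self) == 0:
            raise ValidationError("empty training set")
        classes = set(self.labels.tolist())
        if classes != {0, 1}:
            raise ValidationError(
                f"training needs both classes, got labels {sorted(classes)}")
        shapes = {fm.P.shape for fm in self.features}
        if len(shapes) != 1:
            raise ValidationError(
                f"inconsistent feature shapes: {sorted(shapes)}")


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


@dataclass
class _Params:
    """LSTM + dense weights. Gate order along the 4H axis: i, f, g, o."""

    Wx: np.ndarray  # (D, 4H)
    Wh: np.ndarray  # (H, 4H)
    b: np.ndarray   # (4H,)
    Wd: np.ndarray  # (H, 2)
    bd: np.ndarray  # (2,)

    def flat(self) -> list[np.ndarray]:
        return [self.Wx, self.Wh, self.b, self.Wd, self.bd]


def _init_params(rng: np.random.Generator, d: int, h: int) -> _Params:
    def glorot(shape):
        lim = np.sqrt(6.0 / (shape[0] + shape[1]))
        return rng.uniform(-lim, lim, size=shape)

    b = np.zeros(4 * h)
    b[h:2 * h] = 1.0  # forget-gate bias: remember by default
    return _Params(Wx=glorot((d, 4 * h)), Wh=glorot((h, 4 * h)), b=b,
                   Wd=glorot((h, 2)), bd=np.zeros(2))


def _forward(params: _Params, X: np.ndarray, cache: bool = False):
    """X: (B, T, D) -> softmax probabilities (B, 2), optional BPTT cache."""
    B, T, D = X.shape
    H = params.Wh.shape[0]
    h = np.zeros((B, H))
    c = np.zeros((B, H))
    steps = []
    for t in range(T):
        a = X[:, t] @ params.Wx + h @ params.Wh + params.b
        i = _sigmoid(a[:, :H])
        f = _sigmoid(a[:, H:2 * H])
        g = np.tanh(a[:, 2 * H:3 * H])
        o = _sigmoid(a[:, 3 * H:])
        c_prev = c
        c = f * c_prev + i * g
        tc = np.tanh(c)
        h = o * tc
        if cache:
            steps.append((i, f, g, o, c_prev, tc))
    logits = h @ params.Wd + params.bd
    p = _softmax(logits)
    if cache:
        return p, (h, steps)
    return p


def _backward(params: _Params, X: np.ndarray, y: np.ndarray,
              p: np.ndarray, cache) -> _Params:
    """Gradients of mean cross-entropy w.r.t. all parameters."""
    B, T, D = X.shape
    H = params.Wh.shape[0]
    h_T, steps = cache
    dlogits = (p - np.eye(2)[y]) / B
    grads = _Params(Wx=np.zeros_like(params.Wx), Wh=np.zeros_like(params.Wh),
                    b=np.zeros_like(params.b), Wd=h_T.T @ dlogits,
                    bd=dlogits.sum(axis=0))
    dh = dlogits @ params.Wd.T
    dc = np.zeros((B, H))
    # recompute h_{t-1} from the cache on the way back
    for t in range(T - 1, -1, -1):
        i, f, g, o, c_prev, tc = steps[t]
        do = dh * tc
        dc = dc + dh * o * (1.0 - tc ** 2)
        di = dc * g
        dg = dc * i
        df = dc * c_prev
        da = np.concatenate([
            di * i * (1.0 - i), df * f * (1.0 - f),
            dg * (1.0 - g ** 2), do * o * (1.0 - o)], axis=1)
        if t > 0:
            i_p, f_p, g_p, o_p, c_pp, tc_p = steps[t - 1]
            h_prev = o_p * tc_p
        else:
            h_prev = np.zeros((B, H))
        grads.Wx += X[:, t].T @ da
        grads.Wh += h_prev.T @ da
        grads.b += da.sum(axis=0)
        dh = da @ params.Wh.T
        dc = dc * f
    return grads


def cross_entropy(params: _Params, X: np.ndarray, y: np.ndarray) -> float:
    p = _forward(params, X)
    return float(-np.mean(np.log(p[np.arange(len(y)), y] + 1e-15)))


def numerical_gradient(params: _Params, X: np.ndarray, y: np.ndarray,
                       eps: float = 1e-5) -> _Params:
    """Central-difference gradient of the loss; test oracle for BPTT."""
    grads = []
    for arr in params.flat():
        g = np.zeros_like(arr)
        it = np.nditer(arr, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            orig = arr[idx]
            arr[idx] = orig + eps
            lp = cross_entropy(params, X, y)
            arr[idx] = orig - eps
            lm = cross_entropy(params, X, y)
            arr[idx] = orig
            g[idx] = (lp - lm) / (2 * eps)
        grads.append(g)
    return _Params(*grads)


@dataclass
class WeakLearner:
    params: _Params
    norm_mean: np.ndarray  # (D,)
    norm_std: np.ndarray   # (D,)
    config: LearnerConfig
    input_shape: tuple[int, int]  # (n_rows, n_frames) of the feature matrix

    def normalize(self, P: np.ndarray) -> np.ndarray:
        # sequence layout: (T frames, D rows)
        return (P.T - self.norm_mean) / self.norm_std


def _stack(features: list, norm_mean, norm_std) -> np.ndarray:
    X = np.stack([fm.P.T for fm in features])  # (N, T, D)
    return (X - norm_mean) / norm_std


def train_learner(data: LabeledSet, cfg: LearnerConfig | None = None
                  ) -> WeakLearner:
    """Train one LSTM authenticator; same seed and data give identical
    parameters."""
    cfg = cfg or LearnerConfig()
    cfg.validate()
    data.validate_for_training()
    n_rows, n_frames = data.features[0].P.shape
    if cfg.normalization == "zscore_train":
        flat = np.concatenate([fm.P.T for fm in data.features])  # (N*T, D)
        mean = flat.mean(axis=0)
        std = np.maximum(flat.std(axis=0), 1e-8)
    else:
        mean = np.zeros(n_rows)
        std = np.ones(n_rows)

    X = _stack(data.features, mean, std)
    y = data.labels
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xA11C]))
    params = _init_params(rng, n_rows, cfg.hidden_units)

    m = [np.zeros_like(a) for a in params.flat()]
    v = [np.zeros_like(a) for a in params.flat()]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    n = len(data)
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        for lo in range(0, n, cfg.batch_size):
            idx = order[lo:lo + cfg.batch_size]
            p, cache = _forward(params, X[idx], cache=True)
            grads = _backward(params, X[idx], y[idx], p, cache)
            step += 1
            for a, ga, ma, va in zip(params.flat(), grads.flat(), m, v):
                ma *= beta1
                ma += (1 - beta1) * ga
                va *= beta2
                va += (1 - beta2) * ga ** 2
                mhat = ma / (1 - beta1 ** step)
                vhat = va / (1 - beta2 ** step)
                a -= cfg.learning_rate * mhat / (np.sqrt(vhat) + eps)
    return WeakLearner(params=params, norm_mean=mean, norm_std=std,
                       config=cfg, input_shape=(n_rows, n_frames))


def predict(learner: WeakLearner, features: FeatureMatrix
            ) -> tuple[float, int]:
    """Probability of 'Yes' and the thresholded decision.

    The decision is 1 exactly when p_yes >= decision_threshold (accept at
    the threshold).
    """
    if features.P.shape != learner.input_shape:
        raise ValidationError(
            f"feature shape {features.P.shape} does not match training "
            f"shape {learner.input_shape}")
    X = learner.normalize(features.P)[None]
    p = _forward(learner.params, X)[0]
    p_yes = float(p[1])
    return p_yes, int(p_yes >= learner.config.decision_threshold)


def save_learner(learner: WeakLearner, path) -> None:
    """Single-file container: weights + normalization stats + config."""
    meta = {"format_version": _FORMAT_VERSION,
            "config": asdict(learner.config),
            "input_shape": list(learner.input_shape)}
    np.savez(Path(path),
             Wx=learner.params.Wx, Wh=learner.params.Wh, b=learner.params.b,
             Wd=learner.params.Wd, bd=learner.params.bd,
             norm_mean=learner.norm_mean, norm_std=learner.norm_std,
             meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8))


def load_learner(path) -> WeakLearner:
    with np.load(Path(path)) as z:
        meta = json.loads(bytes(z["meta"].tobytes()).decode())
        if meta["format_version"] != _FORMAT_VERSION:
            raise ValidationError(
                f"unsupported model format {meta['format_version']}")
        params = _Params(Wx=z["Wx"], Wh=z["Wh"], b=z["b"],
                         Wd=z["Wd"], bd=z["bd"])
        return WeakLearner(
            params=params, norm_mean=z["norm_mean"], norm_std=z["norm_std"],
            config=LearnerConfig(**meta["config"]),
            input_shape=tuple(meta["input_shape"]))
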