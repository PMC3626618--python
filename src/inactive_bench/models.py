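"""Native classifiers over fingerprint bits, plus the external-adapter contract.

Three deliberately simple learners are implemented natively -- the trio a
screening benchmark can always fall back on without an external ML stack:

* Bernoulli naive Bayes with Laplace smoothing;
* k-nearest-neighbours by brute-force Euclidean search on bit vectors
  (squared Euclidean distance == Hamming distance, computed exactly on
  packed bits so distance ties are integer-exact);
* Hyperpipes: per class, record which bit values were observed ("the pipe");
  score a query by how many of its bit values the pipe contains.

Prediction tie rules are screening-oriented and documented: score ties go to
"active" for naive Bayes and k-NN votes; Hyperpipes ties go to the class
seen first in training order.  All native models are deterministic.

Heavier algorithms (SVM, ensembles, decision trees) are not re-implemented;
they plug in through :func:`register_adapter` and are treated identically to
native models downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .assembly import LabeledDataset
from .chem import _pack_bits

NATIVE_CLASSIFIERS = ("naive_bayes", "knn", "hyperpipes")

# adapter: (X_train: bool (n, n_bits), y_train: bool) -> predict(X: bool) -> bool
AdapterFactory = Callable[..., Callable[[np.ndarray], np.ndarray]]

_ADAPTERS: dict[str, AdapterFactory] = {}


class SingleClassError(ValueError):
    """Raised when a training set lacks one of the two classes."""


def _check_two_classes(y: np.ndarray) -> None:
    if y.all() or not y.any():
        raise SingleClassError("training set must contain both classes")


@dataclass
class TrainedModel:
    """A fitted classifier: kind, fitted state, and a deterministic predictor."""

    kind: str
    parameters: dict
    train_provenance: dict
    _predict: Callable[[np.ndarray], np.ndarray] = field(repr=False)

    def predict(self, data: LabeledDataset | np.ndarray) -> np.ndarray:
        X = data.bit_matrix() if isinstance(data, LabeledDataset) else np.asarray(data, bool)
        return self._predict(X)

    def to_json(self) -> dict:
        """JSON-serialisable summary (kind, hyperparameters, provenance)."""
        params = {k: v for k, v in self.parameters.items()
                  if isinstance(v, (int, float, str, bool, type(None)))}
        return {"kind": self.kind, "parameters": params,
                "train_provenance": self.train_provenance}


def train_naive_bayes(train: LabeledDataset, alpha: float = 1.0) -> TrainedModel:
    """Bernoulli naive Bayes over fingerprint bits with Laplace smoothing.

    P(bit=1 | class) = (count + alpha) / (n_class + 2*alpha); prediction is
    the argmax of log prior plus per-bit log likelihood, ties -> active.
    """
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    X, y = train.bit_matrix(), train.labels
    _check_two_classes(y)
    n_act, n_inact = int(y.sum()), int((~y).sum())
    p_act = (X[y].sum(axis=0) + alpha) / (n_act + 2 * alpha)
    p_inact = (X[~y].sum(axis=0) + alpha) / (n_inact + 2 * alpha)
    n_total = len(y)
    log_prior = np.log(n_act / n_total) - np.log(n_inact / n_total)
    # decision in a single linear form: w.x + b >= 0 -> active
    w = (np.log(p_act) - np.log(p_inact)) - (np.log1p(-p_act) - np.log1p(-p_inact))
    b = log_prior + (np.log1p(-p_act) - np.log1p(-p_inact)).sum()

    def predict(Xq: np.ndarray) -> np.ndarray:
        return Xq @ w + b >= 0.0

    return TrainedModel(
        kind="naive_bayes",
        parameters={"alpha": alpha, "p_active": p_act, "p_inactive": p_inact,
                    "log_prior_ratio": float(log_prior)},
        train_provenance=dict(train.provenance),
        _predict=predict,
    )


def train_knn(train: LabeledDataset, k: int = 1) -> TrainedModel:
    """k-NN with brute-force Euclidean search on bit vectors.

    Distance ties are broken by training order (stable sort on integer
    Hamming distances); vote ties go to active.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(train):
        raise ValueError(f"k={k} exceeds training size {len(train)}")
    X, y = train.bit_matrix(), train.labels
    packed_train = _pack_bits(X)

    def predict(Xq: np.ndarray) -> np.ndarray:
        packed_q = _pack_bits(np.asarray(Xq, bool))
        out = np.empty(len(packed_q), dtype=bool)
        # keep the (block, n_train, n_words) xor buffer around ~50 MB
        words = packed_train.shape[1]
        block = max(1, 50_000_000 // max(1, len(packed_train) * words))
        for start in range(0, len(packed_q), block):
            stop = min(start + block, len(packed_q))
            xor = packed_q[start:stop, None, :] ^ packed_train[None, :, :]
            d = np.bitwise_count(xor).sum(axis=2, dtype=np.int64)
            nn = np.argsort(d, axis=1, kind="stable")[:, :k]
            votes = y[nn].sum(axis=1)
            out[start:stop] = votes * 2 >= k  # majority, tie -> active
        return out

    return TrainedModel(
        kind="knn",
        parameters={"k": k, "n_train": len(train),
                    "train_ids": [r.id for r in train.records]},
        train_provenance=dict(train.provenance),
        _predict=predict,
    )


def train_hyperpipes(train: LabeledDataset) -> TrainedModel:
    """Hyperpipes: per-class observed-value pipes, containment-count scoring.

    Score of a query for a class = (number of bit positions whose value was
    observed in that class) / n_bits; highest score wins, ties go to the
    class appearing first in training order.
    """
    X, y = train.bit_matrix(), train.labels
    _check_two_classes(y)
    seen1_act, seen0_act = X[y].any(axis=0), (~X[y]).any(axis=0)
    seen1_inact, seen0_inact = X[~y].any(axis=0), (~X[~y]).any(axis=0)
    # class order of first appearance in training order
    first_active = bool(y[0])
    n_bits = X.shape[1]

    def predict(Xq: np.ndarray) -> np.ndarray:
        Xq = np.asarray(Xq, bool)
        score_act = (np.where(Xq, seen1_act, seen0_act)).sum(axis=1) / n_bits
        score_inact = (np.where(Xq, seen1_inact, seen0_inact)).sum(axis=1) / n_bits
        if first_active:
            return score_act >= score_inact
        return score_act > score_inact

    return TrainedModel(
        kind="hyperpipes",
        parameters={"seen1_active": seen1_act, "seen0_active": seen0_act,
                    "seen1_inactive": seen1_inact, "seen0_inactive": seen0_inact,
                    "first_class_active": first_active},
        train_provenance=dict(train.provenance),
        _predict=predict,
    )


# -- external adapter contract ----------------------------------------------

def register_adapter(name: str, factory: AdapterFactory) -> None:
    """Register an external classifier under ``name``.

    ``factory(X_train, y_train, **hyperparameters)`` must return a
    deterministic ``predict(X) -> bool array`` callable.
    """
    _ADAPTERS[name] = factory


def registered_adapters() -> tuple[str, ...]:
    return tuple(sorted(_ADAPTERS))


def external_classifier_adapter(name: str, train: LabeledDataset,
                                **hyperparameters) -> TrainedModel:
    """Fit a registered external classifier; unknown names list the registry."""
    if name not in _ADAPTERS:
        raise KeyError(
            f"no adapter registered under {name!r}; registered adapters: "
            f"{list(registered_adapters()) or 'none'}"
        )
    predict = _ADAPTERS[name](train.bit_matrix(), train.labels, **hyperparameters)
    return TrainedModel(
        kind="external",
        parameters={"adapter": name, **hyperparameters},
        train_provenance=dict(train.provenance),
        _predict=lambda X: np.asarray(predict(np.asarray(X, bool)), dtype=bool),
    )


def train_classifier(name: str, train: LabeledDataset,
                     **hyperparameters) -> TrainedModel:
    """Uniform entry point: native classifiers by name, else the adapter registry."""
    if name == "naive_bayes":
        return train_naive_bayes(train, **hyperparameters)
    if name == "knn":
        return train_knn(train, **hyperparameters)
    if name == "hyperpipes":
        return train_hyperpipes(train, **hyperparameters)
    return external_classifier_adapter(name, train, **hyperparameters)
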