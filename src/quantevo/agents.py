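"""Neural-network agents: each agent encodes one quantifier.

The agent is a small feedforward scorer implemented directly in numpy:

    input(n) -> dense(16), ReLU -> dense(16), ReLU, batch-norm -> dense(1), sigmoid

The second (second-to-last) layer's rectified activations are batch
normalized before reaching the output unit.

mirroring a standard deep-learning stack: fan-in-scaled uniform
initialization for the dense layers, batch normalization over the current
batch, the Adam update rule on a binary cross-entropy loss, and minibatch
iteration with per-epoch reshuffling.  Training and production are pure
functions of the agent's seed and the data, so whole simulations replay
bit-identically.

Production (teaching the next generation) is deterministic: the agent's
canonical confidences are computed in a single batch over the *entire*
structure space — so the normalization statistics are those of the full
space, a fixed reference batch — and the confidence in (0, 1) is rounded,
with the measure-zero tie at exactly 0.5 going to 1.  Normalizing against
the full space rather than frozen running averages matters for untrained
agents: it is what makes a randomly initialized agent speak a varied,
unstructured language (roughly half the structures accepted) instead of a
bias-dominated near-constant one, which is the baseline condition the
simulations start from.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .quantifiers import Quantifier, all_structures

__all__ = ["AgentConfig", "Agent", "init_agent", "respond", "produce_bit", "train_agent", "extract_quantifier"]

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.1
_ADAM_BETAS = (0.9, 0.999)
_ADAM_EPS = 1e-8


@dataclass(frozen=True)
class AgentConfig:
    """Hyperparameters of one agent.

    ``hidden_sizes`` is fixed at (16, 16) by default; ``epochs`` and
    ``batch_size`` govern :func:`train_agent` unless overridden there.
    ``init_scheme`` names the weight initialization (fan-in-scaled uniform,
    the common dense-layer default) and is recorded in run outputs because
    the random-agent baseline distribution depends on it.
    """

    input_size: int
    hidden_sizes: tuple[int, int] = (16, 16)
    epochs: int = 4
    batch_size: int = 32
    optimizer_name: str = "adam"
    learning_rate: float = 1e-3
    init_scheme: str = "fan_in_uniform"
    seed: int = 0


def _init_linear(rng: np.random.Generator, fan_in: int, fan_out: int) -> tuple[np.ndarray, np.ndarray]:
    bound = 1.0 / np.sqrt(fan_in)
    w = rng.uniform(-bound, bound, size=(fan_in, fan_out))
    b = rng.uniform(-bound, bound, size=fan_out)
    return w, b


class Agent:
    """A trainable scorer mapping structures to confidences in (0, 1).

    Use :func:`init_agent` to construct; direct construction from a parameter
    dict is for checkpoint restore.
    """

    def __init__(self, config: AgentConfig, params: dict[str, np.ndarray], rng: np.random.Generator):
        self.config = config
        self.params = params
        self.rng = rng
        self._adam_m: dict[str, np.ndarray] | None = None
        self._adam_v: dict[str, np.ndarray] | None = None
        self._adam_t = 0
        self._canon: np.ndarray | None = None  # cached full-space confidences

    # -- inference ---------------------------------------------------------

    def _forward(self, X: np.ndarray) -> np.ndarray:
        """Forward pass normalizing against the statistics of this batch.

        Batch normalization standardizes the second hidden layer's rectified
        output (dense -> ReLU -> batch-norm -> dense), so an untrained
        agent's scores vary around the decision boundary instead of being
        dominated by accumulated bias terms.
        """
        p = self.params
        a1 = np.maximum(X @ p["W1"] + p["b1"], 0.0)
        r2 = np.maximum(a1 @ p["W2"] + p["b2"], 0.0)
        mu = r2.mean(axis=0)
        var = r2.var(axis=0)
        xhat = (r2 - mu) / np.sqrt(var + _BN_EPS)
        a2 = p["bn_gamma"] * xhat + p["bn_beta"]
        z3 = (a2 @ p["W3"] + p["b3"]).ravel()
        return 1.0 / (1.0 + np.exp(-z3))

    def canonical_confidences(self) -> np.ndarray:
        """Confidence for every structure, computed in one batch over the full
        structure space (the fixed reference batch for normalization)."""
        if self._canon is None:
            X = all_structures(self.config.input_size).astype(np.float64)
            self._canon = self._forward(X)
        return self._canon

    def respond_batch(self, X: np.ndarray) -> np.ndarray:
        """Confidences for the given structures, read off the canonical
        full-space table; deterministic regardless of batch composition."""
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 1:
            X = X[None, :]
        n = self.config.input_size
        if X.shape[1] != n:
            raise ValueError(f"structures have length {X.shape[1]}, agent expects {n}")
        idx = (X.astype(np.int64) @ (2 ** np.arange(n - 1, -1, -1))).astype(np.int64)
        return self.canonical_confidences()[idx]

    def produce_bits(self, X: np.ndarray) -> np.ndarray:
        return self.respond_batch(X) >= 0.5

    # -- training ----------------------------------------------------------

    def _adam_step(self, grads: dict[str, np.ndarray]) -> None:
        lr = self.config.learning_rate
        b1, b2 = _ADAM_BETAS
        if self._adam_m is None:
            self._adam_m = {k: np.zeros_like(v) for k, v in grads.items()}
            self._adam_v = {k: np.zeros_like(v) for k, v in grads.items()}
        self._adam_t += 1
        t = self._adam_t
        for k, g in grads.items():
            m = self._adam_m[k] = b1 * self._adam_m[k] + (1 - b1) * g
            v = self._adam_v[k] = b2 * self._adam_v[k] + (1 - b2) * g * g
            mhat = m / (1 - b1**t)
            vhat = v / (1 - b2**t)
            self.params[k] = self.params[k] - lr * mhat / (np.sqrt(vhat) + _ADAM_EPS)

    def _train_step(self, X: np.ndarray, y: np.ndarray) -> None:
        self._canon = None
        p = self.params
        B = X.shape[0]
        z1 = X @ p["W1"] + p["b1"]
        a1 = np.maximum(z1, 0.0)
        z2 = a1 @ p["W2"] + p["b2"]
        r2 = np.maximum(z2, 0.0)
        mu = r2.mean(axis=0)
        var = r2.var(axis=0)
        inv_std = 1.0 / np.sqrt(var + _BN_EPS)
        xhat = (r2 - mu) * inv_std
        a2 = p["bn_gamma"] * xhat + p["bn_beta"]
        z3 = (a2 @ p["W3"] + p["b3"]).ravel()
        prob = 1.0 / (1.0 + np.exp(-z3))

        # running statistics kept for checkpointing (unbiased variance)
        unbiased = var * (B / (B - 1)) if B > 1 else var
        p["bn_mean"] = (1 - _BN_MOMENTUM) * p["bn_mean"] + _BN_MOMENTUM * mu
        p["bn_var"] = (1 - _BN_MOMENTUM) * p["bn_var"] + _BN_MOMENTUM * unbiased

        # backward pass: mean binary cross-entropy
        dz3 = ((prob - y) / B)[:, None]
        gW3 = a2.T @ dz3
        gb3 = dz3.sum(axis=0)
        da2 = dz3 @ p["W3"].T
        g_gamma = (da2 * xhat).sum(axis=0)
        g_beta = da2.sum(axis=0)
        dxhat = da2 * p["bn_gamma"]
        dr2 = (inv_std / B) * (B * dxhat - dxhat.sum(axis=0) - xhat * (dxhat * xhat).sum(axis=0))
        dz2 = dr2 * (z2 > 0.0)
        da1 = dz2 @ p["W2"].T
        dz1 = da1 * (z1 > 0.0)
        grads = {
            "W1": X.T @ dz1,
            "b1": dz1.sum(axis=0),
            "W2": a1.T @ dz2,
            "b2": dz2.sum(axis=0),
            "bn_gamma": g_gamma,
            "bn_beta": g_beta,
            "W3": gW3,
            "b3": gb3,
        }
        self._adam_step(grads)

    # -- persistence -------------------------------------------------------

    def checkpoint(self) -> dict[str, np.ndarray]:
        """Flat named-array snapshot of all parameters and normalization statistics."""
        return {k: v.copy() for k, v in self.params.items()}


def init_agent(config: AgentConfig, seed: int | None = None) -> Agent:
    """Freshly initialized agent, fully reproducible from ``seed``
    (``config.seed`` when not given)."""
    h1, h2 = config.hidden_sizes
    if config.optimizer_name != "adam":
        raise ValueError(f"unsupported optimizer {config.optimizer_name!r}")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.input_size
    W1, b1 = _init_linear(rng, n, h1)
    W2, b2 = _init_linear(rng, h1, h2)
    W3, b3 = _init_linear(rng, h2, 1)
    params = {
        "W1": W1, "b1": b1,
        "W2": W2, "b2": b2,
        "bn_gamma": np.ones(h2), "bn_beta": np.zeros(h2),
        "bn_mean": np.zeros(h2), "bn_var": np.ones(h2),
        "W3": W3, "b3": b3,
    }
    return Agent(config, params, rng)


def respond(agent: Agent, structure: np.ndarray) -> float:
    """The agent's confidence in (0, 1) that the structure verifies its quantifier."""
    return float(agent.respond_batch(np.asarray(structure, dtype=bool))[0])


def produce_bit(agent: Agent, structure: np.ndarray) -> int:
    """Deterministic production: the rounded confidence (ties at 0.5 go to 1)."""
    return int(respond(agent, structure) >= 0.5)


def train_agent(
    agent: Agent,
    examples: tuple[np.ndarray, np.ndarray] | list[tuple[np.ndarray, int]],
    epochs: int | None = None,
    batch_size: int | None = None,
) -> Agent:
    """Minibatch training on (structure, bit) pairs; modifies ``agent`` in place
    and returns it.

    ``examples`` is either a pair of arrays ``(X, y)`` with ``X`` of shape
    (m, n), or a list of (structure, bit) tuples.  The data order is
    reshuffled every epoch using the agent's own random stream.
    """
    if isinstance(examples, tuple) and len(examples) == 2 and not isinstance(examples[0], tuple):
        X = np.asarray(examples[0], dtype=np.float64)
        y = np.asarray(examples[1], dtype=np.float64)
    else:
        if len(examples) == 0:
            raise ValueError("training requires at least one example")
        X = np.asarray([np.asarray(s, dtype=float) for s, _ in examples])
        y = np.asarray([float(b) for _, b in examples])
    if X.size == 0:
        raise ValueError("training requires at least one example")
    if X.ndim != 2 or X.shape[1] != agent.config.input_size:
        raise ValueError(f"training structures must have length {agent.config.input_size}")
    epochs = agent.config.epochs if epochs is None else epochs
    batch_size = agent.config.batch_size if batch_size is None else batch_size
    m = X.shape[0]
    for _ in range(epochs):
        order = agent.rng.permutation(m)
        for start in range(0, m, batch_size):
            sl = order[start : start + batch_size]
            agent._train_step(X[sl], y[sl])
    return agent


def extract_quantifier(agent: Agent) -> Quantifier:
    """The full truth table the agent would produce, as a :class:`Quantifier`."""
    X = all_structures(agent.config.input_size)
    return Quantifier(agent.produce_bits(X))
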