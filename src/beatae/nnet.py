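"""Minimal dense feed-forward core for the four model archetypes.

The same machinery expresses

* a plain undercomplete autoencoder (AE): trunk ``[L, code, L]``,
  mean-squared reconstruction error;
* a sparse autoencoder (SAE): the same trunk with an L1 activity penalty
  on the code layer;
* a supervised autoencoder (SupAE): the SAE plus a small sigmoid
  classifier head attached at the code (optionally concatenated with
  auxiliary inputs such as the LCSD value), trained jointly on
  reconstruction (MSE) and classification (binary cross-entropy);
* a bare MLP classifier: an empty trunk (the "code" is the input itself)
  with only the head.

Everything is plain numpy: analytic backpropagation, Adam updates on
shuffled mini-batches, early stopping on validation loss, full seeded
determinism.  Networks this size (tens to hundreds of parameters) train
in seconds on one CPU, which is the point of the approach.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NetworkSpec",
    "Network",
    "TrainConfig",
    "TrainResult",
    "build_network",
    "train",
    "ae_spec",
    "sae_spec",
    "supae_spec",
    "mlp_spec",
    "logistic_spec",
    "code_width",
]

_EPS = 1e-12  # probability clipping for BCE


def _act(name: str, z: np.ndarray) -> np.ndarray:
    if name == "linear":
        return z
    if name == "relu":
        return np.maximum(z, 0.0)
    if name == "tanh":
        return np.tanh(z)
    if name == "sigmoid":
        return 1.0 / (1.0 + np.exp(-z))
    raise ValueError(f"unknown activation {name!r}")


def _act_grad(name: str, a: np.ndarray) -> np.ndarray:
    """Derivative expressed through the activation value ``a``."""
    if name == "linear":
        return np.ones_like(a)
    if name == "relu":
        return (a > 0).astype(a.dtype)
    if name == "tanh":
        return 1.0 - a * a
    if name == "sigmoid":
        return a * (1.0 - a)
    raise ValueError(f"unknown activation {name!r}")


def code_width(input_width: int, compression: float = 0.75) -> int:
    """Code width for a given compression level (default 75% -> code is
    25% of the input)."""
    return int(round((1.0 - compression) * input_width))


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture + loss configuration.

    ``trunk`` is the ordered autoencoder path (input ... code ... output);
    a single-element trunk means no autoencoder (the input is the code).
    ``head`` widths, if any, form the classifier applied to
    ``concat(code, aux)``; the final head activation must be sigmoid.
    The total loss is ``w_rec*MSE + w_cls*BCE + l1_code*mean(|code|)``.
    """

    trunk: tuple
    code_index: int
    trunk_activations: tuple = ()
    head: tuple = ()
    head_activations: tuple = ()
    aux_dim: int = 0
    w_rec: float = 1.0
    w_cls: float = 0.0
    l1_code: float = 0.0
    head_loss: str = "bce"   # "bce" (sigmoid output) or "mse" (linear output)

    def __post_init__(self):
        if len(self.trunk) < 1:
            raise ValueError("trunk needs at least the input width")
        if not (0 <= self.code_index < len(self.trunk)):
            raise ValueError("code_index outside trunk")
        if len(self.trunk_activations) != len(self.trunk) - 1:
            raise ValueError("need one trunk activation per layer")
        if len(self.head_activations) != len(self.head):
            raise ValueError("need one head activation per head layer")
        if len(self.trunk) > 1:
            if tuple(self.trunk) != tuple(reversed(self.trunk)):
                raise ValueError("autoencoder trunk must be symmetric about the code")
            if self.code_index != (len(self.trunk) - 1) // 2:
                raise ValueError("code_index must sit at the trunk's center")
        if self.head_loss not in ("bce", "mse"):
            raise ValueError("head_loss must be 'bce' or 'mse'")
        if self.head and self.head_loss == "bce" and self.head_activations[-1] != "sigmoid":
            raise ValueError("classifier head must end in a sigmoid")
        if self.head and self.head_loss == "mse" and self.head_activations[-1] != "linear":
            raise ValueError("regression head must end in a linear layer")
        if self.l1_code < 0 or self.w_rec < 0 or self.w_cls < 0:
            raise ValueError("loss weights must be non-negative")

    @property
    def input_width(self) -> int:
        return self.trunk[0]

    @property
    def code_dim(self) -> int:
        return self.trunk[self.code_index]

    @property
    def has_decoder(self) -> bool:
        return len(self.trunk) > 1

    @property
    def layer_shapes(self) -> list:
        shapes = [
            (self.trunk[i], self.trunk[i + 1]) for i in range(len(self.trunk) - 1)
        ]
        if self.head:
            widths = [self.code_dim + self.aux_dim, *self.head]
            shapes += [(widths[i], widths[i + 1]) for i in range(len(self.head))]
        return shapes

    @property
    def n_parameters(self) -> int:
        """Trainable parameter count: sum of fan_in*fan_out + fan_out."""
        return sum(fi * fo + fo for fi, fo in self.layer_shapes)

    def to_json(self) -> str:
        return json.dumps(
            {
                "trunk": list(self.trunk),
                "code_index": self.code_index,
                "trunk_activations": list(self.trunk_activations),
                "head": list(self.head),
                "head_activations": list(self.head_activations),
                "aux_dim": self.aux_dim,
                "w_rec": self.w_rec,
                "w_cls": self.w_cls,
                "l1_code": self.l1_code,
                "head_loss": self.head_loss,
            }
        )

    @staticmethod
    def from_json(blob: str) -> "NetworkSpec":
        d = json.loads(blob)
        return NetworkSpec(
            trunk=tuple(d["trunk"]),
            code_index=d["code_index"],
            trunk_activations=tuple(d["trunk_activations"]),
            head=tuple(d["head"]),
            head_activations=tuple(d["head_activations"]),
            aux_dim=d["aux_dim"],
            w_rec=d["w_rec"],
            w_cls=d["w_cls"],
            l1_code=d["l1_code"],
            head_loss=d.get("head_loss", "bce"),
        )


# ---------------------------------------------------------------- presets

def ae_spec(input_width: int, compression: float = 0.75) -> NetworkSpec:
    """Undercomplete AE: [L, round((1-compression)*L), L], tanh code,
    linear output (inputs are standardized)."""
    return NetworkSpec(
        trunk=(input_width, code_width(input_width, compression), input_width),
        code_index=1,
        trunk_activations=("tanh", "linear"),
        w_rec=1.0,
    )


def sae_spec(
    input_width: int, compression: float = 0.75, l1_code: float = 1e-4
) -> NetworkSpec:
    """Sparse AE: the AE preset with an L1 activity penalty on the code."""
    base = ae_spec(input_width, compression)
    return NetworkSpec(
        trunk=base.trunk,
        code_index=base.code_index,
        trunk_activations=base.trunk_activations,
        l1_code=l1_code,
        w_rec=1.0,
    )


def supae_spec(
    input_width: int,
    compression: float = 0.75,
    l1_code: float = 1e-4,
    aux_dim: int = 0,
    head: tuple = (3, 1),
    w_rec: float = 1.0,
    w_cls: float = 1.0,
) -> NetworkSpec:
    """Supervised sparse AE: classifier head at the bottleneck, joint
    MSE + BCE loss.  ``aux_dim`` extra inputs (e.g. LCSD) are
    concatenated to the code before the head."""
    base = sae_spec(input_width, compression, l1_code)
    return NetworkSpec(
        trunk=base.trunk,
        code_index=base.code_index,
        trunk_activations=base.trunk_activations,
        head=tuple(head),
        head_activations=("tanh",) * (len(head) - 1) + ("sigmoid",),
        aux_dim=aux_dim,
        w_rec=w_rec,
        w_cls=w_cls,
        l1_code=l1_code,
    )


def mlp_spec(input_dim: int, head: tuple = (3, 1)) -> NetworkSpec:
    """Stand-alone classifier on a feature vector (code + LCSD)."""
    return NetworkSpec(
        trunk=(input_dim,),
        code_index=0,
        trunk_activations=(),
        head=tuple(head),
        head_activations=("tanh",) * (len(head) - 1) + ("sigmoid",),
        w_rec=0.0,
        w_cls=1.0,
    )


def logistic_spec(input_dim: int = 1) -> NetworkSpec:
    """Zero-hidden-layer classifier: plain logistic regression."""
    return NetworkSpec(
        trunk=(input_dim,),
        code_index=0,
        trunk_activations=(),
        head=(1,),
        head_activations=("sigmoid",),
        w_rec=0.0,
        w_cls=1.0,
    )


# ---------------------------------------------------------------- network

class Network:
    """Dense network instantiating a :class:`NetworkSpec`.

    Weights are initialized from a seeded uniform distribution scaled by
    ``1/sqrt(fan_in)``.  All arithmetic is float64.
    """

    def __init__(self, spec: NetworkSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for fan_in, fan_out in spec.layer_shapes:
            bound = 1.0 / np.sqrt(fan_in)
            self.weights.append(rng.uniform(-bound, bound, (fan_in, fan_out)))
            self.biases.append(np.zeros(fan_out))
        self._n_trunk = len(spec.trunk) - 1

    # -- parameter flattening (used by Adam and by gradient checks) -----

    def get_params(self) -> np.ndarray:
        return np.concatenate(
            [w.ravel() for w in self.weights] + [b.ravel() for b in self.biases]
        )

    def set_params(self, flat: np.ndarray) -> None:
        i = 0
        for k, w in enumerate(self.weights):
            self.weights[k] = flat[i : i + w.size].reshape(w.shape).copy()
            i += w.size
        for k, b in enumerate(self.biases):
            self.biases[k] = flat[i : i + b.size].copy()
            i += b.size

    def copy_weights(self) -> tuple:
        return ([w.copy() for w in self.weights], [b.copy() for b in self.biases])

    def load_weights(self, snapshot: tuple) -> None:
        ws, bs = snapshot
        self.weights = [w.copy() for w in ws]
        self.biases = [b.copy() for b in bs]

    # -- forward ---------------------------------------------------------

    def _forward_cache(self, x: np.ndarray, aux: np.ndarray | None):
        spec = self.spec
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[1] != spec.input_width:
            raise ValueError(
                f"input width {x.shape[1]} != spec input {spec.input_width}"
            )
        trunk_acts = [x]
        a = x
        for i in range(self._n_trunk):
            z = a @ self.weights[i] + self.biases[i]
            a = _act(spec.trunk_activations[i], z)
            trunk_acts.append(a)
        code = trunk_acts[spec.code_index]
        recon = trunk_acts[-1] if spec.has_decoder else None

        head_acts = None
        prob = None
        if spec.head:
            if spec.aux_dim:
                if aux is None:
                    raise ValueError("network expects auxiliary inputs")
                aux = np.atleast_2d(np.asarray(aux, dtype=float))
                if aux.shape != (x.shape[0], spec.aux_dim):
                    raise ValueError("auxiliary input shape mismatch")
                h = np.concatenate([code, aux], axis=1)
            else:
                h = code
            head_acts = [h]
            for j in range(len(spec.head)):
                k = self._n_trunk + j
                z = h @ self.weights[k] + self.biases[k]
                h = _act(spec.head_activations[j], z)
                head_acts.append(h)
            prob = head_acts[-1][:, 0]
        return trunk_acts, head_acts, code, recon, prob

    def forward(self, x: np.ndarray, aux: np.ndarray | None = None):
        """Return ``(reconstruction, probability, code)``; entries are
        None where the architecture lacks that output."""
        _, _, code, recon, prob = self._forward_cache(x, aux)
        return recon, prob, code

    def encode(self, x: np.ndarray, ) -> np.ndarray:
        """Code vectors for a batch (the morphological feature vectors)."""
        _, _, code, _, _ = self._forward_cache(
            x, np.zeros((np.atleast_2d(x).shape[0], self.spec.aux_dim))
            if self.spec.aux_dim else None,
        )
        return code

    def predict_proba(self, x: np.ndarray, aux: np.ndarray | None = None) -> np.ndarray:
        _, prob, _ = self.forward(x, aux)
        if prob is None:
            raise ValueError("network has no classifier head")
        return prob

    # -- loss and gradients ----------------------------------------------

    def loss(
        self,
        x: np.ndarray,
        labels: np.ndarray | None = None,
        aux: np.ndarray | None = None,
    ) -> tuple[float, dict]:
        """Total loss and its components on a batch.

        MSE averages over batch and features, BCE over the batch, the L1
        term over batch and code units.  Labels are required iff the spec
        has a classifier head with ``w_cls > 0``.
        """
        _, _, code, recon, prob = self._forward_cache(x, aux)
        x2 = np.atleast_2d(np.asarray(x, dtype=float))
        parts = {"mse": 0.0, "bce": 0.0, "l1": 0.0}
        total = 0.0
        if self.spec.has_decoder and self.spec.w_rec > 0:
            parts["mse"] = float(np.mean((recon - x2) ** 2))
            total += self.spec.w_rec * parts["mse"]
        if self.spec.head and self.spec.w_cls > 0:
            if labels is None:
                raise ValueError("labels required for the supervised loss")
            y = np.asarray(labels, dtype=float).ravel()
            if self.spec.head_loss == "bce":
                p = np.clip(prob, _EPS, 1 - _EPS)
                parts["bce"] = float(
                    -np.mean(y * np.log(p) + (1 - y) * np.log(1 - p))
                )
                total += self.spec.w_cls * parts["bce"]
            else:
                parts["head_mse"] = float(np.mean((prob - y) ** 2))
                total += self.spec.w_cls * parts["head_mse"]
        if self.spec.l1_code > 0:
            parts["l1"] = float(np.mean(np.abs(code)))
            total += self.spec.l1_code * parts["l1"]
        return total, parts

    def backprop_gradients(
        self,
        x: np.ndarray,
        labels: np.ndarray | None = None,
        aux: np.ndarray | None = None,
    ) -> tuple[list[np.ndarray], list[np.ndarray]]:
        """Analytic gradients of the total loss w.r.t. weights and biases."""
        spec = self.spec
        trunk_acts, head_acts, code, recon, prob = self._forward_cache(x, aux)
        x2 = trunk_acts[0]
        batch = x2.shape[0]
        gw = [np.zeros_like(w) for w in self.weights]
        gb = [np.zeros_like(b) for b in self.biases]

        # gradient arriving at the code activation
        d_code = np.zeros_like(code)
        if spec.l1_code > 0:
            d_code += spec.l1_code * np.sign(code) / code.size

        # head: BCE through the final sigmoid fuses to (p - y); for a
        # linear MSE head the same shape holds up to the factor 2
        if spec.head and spec.w_cls > 0:
            if labels is None:
                raise ValueError("labels required for the supervised loss")
            y = np.asarray(labels, dtype=float).ravel()
            factor = 1.0 if spec.head_loss == "bce" else 2.0
            delta = (factor * spec.w_cls * (prob - y) / batch)[:, None]
            for j in range(len(spec.head) - 1, -1, -1):
                k = self._n_trunk + j
                a_prev = head_acts[j]
                if j < len(spec.head) - 1:
                    delta = delta * _act_grad(spec.head_activations[j], head_acts[j + 1])
                gw[k] += a_prev.T @ delta
                gb[k] += delta.sum(axis=0)
                delta = delta @ self.weights[k].T
            d_code += delta[:, : spec.code_dim]

        # decoder: MSE back to the code
        if spec.has_decoder and spec.w_rec > 0:
            delta = spec.w_rec * 2.0 * (recon - x2) / recon.size
            for i in range(self._n_trunk - 1, spec.code_index - 1, -1):
                delta = delta * _act_grad(spec.trunk_activations[i], trunk_acts[i + 1])
                gw[i] += trunk_acts[i].T @ delta
                gb[i] += delta.sum(axis=0)
                delta = delta @ self.weights[i].T
            d_code += delta

        # encoder
        delta = d_code
        for i in range(spec.code_index - 1, -1, -1):
            delta = delta * _act_grad(spec.trunk_activations[i], trunk_acts[i + 1])
            gw[i] += trunk_acts[i].T @ delta
            gb[i] += delta.sum(axis=0)
            delta = delta @ self.weights[i].T
        return gw, gb


def build_network(spec: NetworkSpec, seed: int = 0) -> Network:
    """Instantiate a spec with seeded initialization."""
    return Network(spec, seed=seed)


# ---------------------------------------------------------------- training

@dataclass(frozen=True)
class TrainConfig:
    """Training protocol: Adam (lr 1e-4, beta1 0.9, beta2 0.999,
    eps 1e-8) on shuffled batches of 32, at most 2000 epochs, early
    stopping after 50 epochs without a validation-loss decrease."""

    batch_size: int = 32
    learning_rate: float = 1e-4
    max_epochs: int = 2000
    patience: int = 50
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    seed: int = 0

    def __post_init__(self):
        if min(self.batch_size, self.learning_rate, self.max_epochs, self.patience) <= 0:
            raise ValueError("training parameters must be positive")
        if self.patience >= self.max_epochs:
            raise ValueError("patience must be smaller than max_epochs")


@dataclass
class TrainResult:
    """Loss curves and the selected (best-validation) instance."""

    train_losses: list = field(default_factory=list)
    val_losses: list = field(default_factory=list)
    val_components: list = field(default_factory=list)  # dicts per epoch
    best_epoch: int = -1
    best_val_loss: float = np.inf
    epochs_run: int = 0
    stop_reason: str = ""
    best_weights: tuple | None = None

    def curves_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("epoch,train_loss,val_loss,val_mse,val_bce,val_l1\n")
            for e, (tr, vl, comp) in enumerate(
                zip(self.train_losses, self.val_losses, self.val_components)
            ):
                fh.write(
                    f"{e},{tr:.9g},{vl:.9g},{comp.get('mse', 0.0):.9g},"
                    f"{comp.get('bce', 0.0):.9g},{comp.get('l1', 0.0):.9g}\n"
                )


def train(
    network: Network,
    train_data: tuple,
    val_data: tuple,
    config: TrainConfig = TrainConfig(),
) -> TrainResult:
    """Mini-batch Adam with early stopping on validation loss.

    ``train_data``/``val_data`` are ``(x, labels, aux)`` tuples; labels
    and aux may be None when the spec does not use them.  The network is
    left holding the weights of the best-validation epoch, which are also
    stored in the result.  Fully deterministic given ``config.seed``.
    """
    x_tr, y_tr, aux_tr = train_data
    x_va, y_va, aux_va = val_data
    x_tr = np.atleast_2d(np.asarray(x_tr, dtype=float))
    x_va = np.atleast_2d(np.asarray(x_va, dtype=float))
    if x_tr.shape[0] == 0 or x_va.shape[0] == 0:
        raise ValueError("training and validation sets must be non-empty")

    rng = np.random.default_rng(config.seed)
    n = x_tr.shape[0]
    flat = network.get_params()
    m = np.zeros_like(flat)
    v = np.zeros_like(flat)
    t = 0
    result = TrainResult()
    since_best = 0

    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb = x_tr[idx]
            yb = None if y_tr is None else np.asarray(y_tr)[idx]
            ab = None if aux_tr is None else np.atleast_2d(np.asarray(aux_tr))[idx]
            total, _ = network.loss(xb, yb, ab)
            gw, gb = network.backprop_gradients(xb, yb, ab)
            grad = np.concatenate(
                [g.ravel() for g in gw] + [g.ravel() for g in gb]
            )
            t += 1
            m = config.beta1 * m + (1 - config.beta1) * grad
            v = config.beta2 * v + (1 - config.beta2) * grad * grad
            m_hat = m / (1 - config.beta1**t)
            v_hat = v / (1 - config.beta2**t)
            flat = flat - config.learning_rate * m_hat / (np.sqrt(v_hat) + config.eps)
            network.set_params(flat)
            epoch_losses.append(total)

        val_total, val_parts = network.loss(x_va, y_va, aux_va)
        result.train_losses.append(float(np.mean(epoch_losses)))
        result.val_losses.append(val_total)
        result.val_components.append(val_parts)
        result.epochs_run = epoch + 1

        if val_total < result.best_val_loss:
            result.best_val_loss = val_total
            result.best_epoch = epoch
            result.best_weights = network.copy_weights()
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.patience:
                result.stop_reason = "early_stopping"
                break
    else:
        result.stop_reason = "max_epochs"

    network.load_weights(result.best_weights)
    return result


def save_network(network: Network, path) -> None:
    """Persist weights + spec as an NPZ bundle."""
    arrays = {f"w{i}": w for i, w in enumerate(network.weights)}
    arrays.update({f"b{i}": b for i, b in enumerate(network.biases)})
    arrays["spec_json"] = np.array(network.spec.to_json())
    np.savez(path, **arrays)


def load_network(path) -> Network:
    with np.load(path, allow_pickle=False) as z:
        spec = NetworkSpec.from_json(str(z["spec_json"]))
        net = Network(spec, seed=0)
        net.weights = [z[f"w{i}"] for i in range(len(net.weights))]
        net.biases = [z[f"b{i}"] for i in range(len(net.biases))]
    return net
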