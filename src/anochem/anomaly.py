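"""Fingerprint autoencoder for structural anomaly detection.

An autoencoder is trained to reconstruct ECFP4 fingerprints of real
molecules; a structure whose fingerprint the model cannot reproduce is
flagged as anomalous. The loss is per-bit binary cross-entropy, and the
per-molecule score is the cosine recovery score

    S_C(x, x') = x . x' / (||x|| ||x'||)

between the input bit vector x and its sigmoid reconstruction x'.
Because both vectors are elementwise non-negative, S_C is in [0, 1];
downstream this value is the ensemble feature ``l_ecfp4``.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field, asdict

import numpy as np

from ._nn import MLP
from .chem import Fingerprint

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AutoencoderSpec:
    """Hyperparameters of one grid cell.

    ``layer_widths`` lists the encoder widths ending at the bottleneck;
    the decoder mirrors them back up to the input width.
    """

    layer_widths: tuple[int, ...] = (1024, 256)
    learning_rate: float = 1e-3
    batch_size: int = 128
    max_epochs: int = 30
    patience: int = 5
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "layer_widths", tuple(int(w) for w in self.layer_widths))
        if any(w <= 0 for w in self.layer_widths):
            raise ValueError("layer widths must be positive")

    def layer_sizes(self, n_bits: int) -> tuple[int, ...]:
        if self.layer_widths[-1] >= n_bits:
            raise ValueError("bottleneck must be narrower than the input")
        enc = list(self.layer_widths)
        dec = list(reversed(enc[:-1]))
        return tuple([n_bits] + enc + dec + [n_bits])


#: Default grid: widths x learning rates covering the tunable knobs
#: (nodes, depth, learning rate) at desk scale.
DEFAULT_GRID: tuple[AutoencoderSpec, ...] = tuple(
    AutoencoderSpec(layer_widths=w, learning_rate=lr)
    for w in ((1024, 256), (512, 128), (1024, 128))
    for lr in (1e-3, 1e-4)
)


@dataclass
class TrainedAnomalyModel:
    spec: AutoencoderSpec
    net: MLP = field(repr=False)
    train_loss: float  # mean per-bit BCE on the training fraction
    test_loss: float  # mean per-bit BCE on the held-out fraction
    n_bits: int

    def reconstruct(self, fps: np.ndarray) -> np.ndarray:
        """Sigmoid reconstructions in (0, 1), one row per fingerprint."""
        fps = np.atleast_2d(np.asarray(fps))
        if fps.shape[1] != self.n_bits:
            raise ValueError(f"fingerprint width {fps.shape[1]} != model width {self.n_bits}")
        return self.net.predict(fps.astype(np.float32))


def _train_one(
    spec: AutoencoderSpec, X_tr: np.ndarray, X_val: np.ndarray, init_seed: int
) -> tuple[MLP, float, float]:
    """Train one grid cell with early stopping on held-out BCE."""
    net = MLP(spec.layer_sizes(X_tr.shape[1]), seed=init_seed)
    rng = np.random.default_rng(init_seed + 1)
    best = {"val": np.inf, "train": np.inf, "state": net.state_dict()}
    stale = 0
    for _ in range(spec.max_epochs):
        train_loss = net.fit_epoch(X_tr, X_tr, spec.learning_rate, spec.batch_size, rng)
        val_loss = net.loss(X_val, X_val)
        if not np.isfinite(val_loss) or not np.isfinite(train_loss):
            raise FloatingPointError("non-finite loss")
        if val_loss < best["val"] - 1e-6:
            best = {"val": val_loss, "train": train_loss, "state": net.state_dict()}
            stale = 0
        else:
            stale += 1
            if stale >= spec.patience:
                break
    net.load_state_dict(best["state"])
    return net, float(best["train"]), float(best["val"])


def train_autoencoder(
    real_fps: np.ndarray,
    grid: tuple[AutoencoderSpec, ...] | list[AutoencoderSpec] | None = None,
    val_fraction: float = 0.2,
    seed: int = 0,
) -> TrainedAnomalyModel:
    """Grid-search the autoencoder on fingerprints of real molecules.

    The training matrix is split 4:1 into train/held-out (seeded); each
    grid cell trains with early stopping and the cell with the lowest
    held-out reconstruction loss wins. Cells whose loss goes non-finite
    are skipped; if every cell fails an error is raised.
    """
    X = np.asarray(real_fps, dtype=np.float32)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 training fingerprints")
    grid = tuple(grid) if grid else DEFAULT_GRID
    if not grid:
        raise ValueError("empty hyperparameter grid")
    rng = np.random.default_rng(seed)
    order = rng.permutation(X.shape[0])
    n_val = int(round(val_fraction * X.shape[0]))
    if n_val >= X.shape[0]:
        n_val = X.shape[0] - 1
    if n_val == 0:  # val_fraction 0: monitor the training data itself
        X_tr = X_val = X
    else:
        X_val, X_tr = X[order[:n_val]], X[order[n_val:]]

    best: TrainedAnomalyModel | None = None
    for i, spec in enumerate(grid):
        init_seed = (spec.seed + 7919 * seed + 104729 * i) % (2**31 - 1)
        try:
            net, tr_loss, val_loss = _train_one(spec, X_tr, X_val, init_seed)
        except FloatingPointError:
            logger.warning("grid cell %s diverged (non-finite loss); skipped", spec)
            continue
        logger.info("AE cell widths=%s lr=%g: held-out loss %.5f", spec.layer_widths,
                    spec.learning_rate, val_loss)
        if best is None or val_loss < best.test_loss:
            best = TrainedAnomalyModel(spec=spec, net=net, train_loss=tr_loss,
                                       test_loss=val_loss, n_bits=X.shape[1])
    if best is None:
        raise RuntimeError("every autoencoder grid cell failed")
    return best


def recovery_score(model: TrainedAnomalyModel, fp: Fingerprint | np.ndarray) -> float:
    """Cosine similarity between a fingerprint and its reconstruction."""
    x = fp.bits if isinstance(fp, Fingerprint) else np.asarray(fp)
    x = x.astype(np.float64).ravel()
    if x.shape[0] != model.n_bits:
        raise ValueError(f"fingerprint width {x.shape[0]} != model width {model.n_bits}")
    nx = np.linalg.norm(x)
    if nx == 0:
        raise ValueError("all-zero fingerprint: cosine recovery undefined")
    r = model.reconstruct(x[None, :]).ravel().astype(np.float64)
    return float(x @ r / (nx * np.linalg.norm(r)))


def score_batch(model: TrainedAnomalyModel, fps: np.ndarray) -> np.ndarray:
    """Vectorized recovery scores, identical to mapping :func:`recovery_score`."""
    fps = np.asarray(fps)
    if fps.size == 0:
        return np.zeros(0, dtype=np.float64)
    fps = np.atleast_2d(fps)
    X = fps.astype(np.float64)
    norms = np.linalg.norm(X, axis=1)
    if np.any(norms == 0):
        raise ValueError("all-zero fingerprint in batch: cosine recovery undefined")
    R = model.reconstruct(fps).astype(np.float64)
    return np.einsum("ij,ij->i", X, R) / (norms * np.linalg.norm(R, axis=1))


# -------------------------------------------------------------- persistence


def save_model(model: TrainedAnomalyModel, path: str) -> None:
    """Persist as a directory: JSON spec + npz weight arrays."""
    os.makedirs(path, exist_ok=True)
    meta = {
        "spec": asdict(model.spec),
        "train_loss": model.train_loss,
        "test_loss": model.test_loss,
        "n_bits": model.n_bits,
    }
    with open(os.path.join(path, "spec.json"), "w") as fh:
        json.dump(meta, fh, indent=2)
    np.savez(os.path.join(path, "weights.npz"), **model.net.state_dict())


def load_model(path: str) -> TrainedAnomalyModel:
    with open(os.path.join(path, "spec.json")) as fh:
        meta = json.load(fh)
    spec = AutoencoderSpec(**{**meta["spec"], "layer_widths": tuple(meta["spec"]["layer_widths"])})
    net = MLP(spec.layer_sizes(meta["n_bits"]))
    with np.load(os.path.join(path, "weights.npz")) as z:
        net.load_state_dict({k: z[k] for k in z.files})
    return TrainedAnomalyModel(spec=spec, net=net, train_loss=meta["train_loss"],
                               test_loss=meta["test_loss"], n_bits=meta["n_bits"])
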