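"""Column embeddings for categorical features and autoencoder pre-training.

Each categorical column owns an embedding table with one row per category
(including the reserved unknown slot).  Embeddings can be initialised
randomly or pre-trained without labels: an autoencoder

    h = f(W_e x + b_e),    x_hat = g(W_d h + b_d)

is trained to reconstruct the concatenated one-hot indicator vectors of a
dataset's categorical columns under a mean-squared-error objective

    Loss = (1/N) * sum_i || x_i - x_hat_i ||^2 .

Because the inputs are indicator vectors, the encoder image of indicator
``e_j`` — row ``j`` of ``W_e`` (in the row-vector convention used here)
plus ``b_e``, passed through ``f`` — is exactly the learned representation
of category ``j``, and becomes its embedding row.  Row-vector convention
throughout: ``h = f(x @ W_e + b_e)`` with ``W_e`` of shape ``(M, D)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .autodiff import Adam, Tensor, matmul, relu, tmean, tsum
from . import autodiff as ad
from .preprocess import EncodedDataset

__all__ = [
    "ColumnEmbedding",
    "AutoencoderParams",
    "init_embeddings",
    "lookup",
    "autoencoder_forward",
    "reconstruction_loss",
    "pretrain_embeddings",
]

_ACTIVATIONS = {
    "relu": lambda x: np.maximum(x, 0.0),
    "identity": lambda x: x,
}


@dataclass
class ColumnEmbedding:
    """Per-column embedding tables sharing one embedding dimension."""

    matrices: list[np.ndarray]      # one (N_j, D) table per categorical column
    column_names: list[str]
    dim: int

    def __post_init__(self) -> None:
        for name, m in zip(self.column_names, self.matrices):
            if m.shape[1] != self.dim:
                raise ValueError(
                    f"embedding for column {name!r} has dim {m.shape[1]}, "
                    f"expected {self.dim}")

    @property
    def cardinalities(self) -> list[int]:
        return [m.shape[0] for m in self.matrices]

    def save(self, path: str | Path) -> None:
        path = Path(path)
        arrays = {f"emb_{i}": m for i, m in enumerate(self.matrices)}
        np.savez(path, **arrays)
        manifest = {"column_names": self.column_names, "dim": self.dim,
                    "cardinalities": self.cardinalities}
        path.with_suffix(".json").write_text(
            json.dumps(manifest, indent=2) + "\n", encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "ColumnEmbedding":
        path = Path(path)
        manifest = json.loads(path.with_suffix(".json").read_text(encoding="utf-8"))
        with np.load(path) as npz:
            matrices = [npz[f"emb_{i}"]
                        for i in range(len(manifest["column_names"]))]
        return cls(matrices=matrices, column_names=manifest["column_names"],
                   dim=manifest["dim"])


@dataclass
class AutoencoderParams:
    """Encoder/decoder weights in the row-vector convention."""

    W_e: np.ndarray      # (M, D)
    b_e: np.ndarray      # (D,)
    W_d: np.ndarray      # (D, M)
    b_d: np.ndarray      # (M,)
    f: str = "relu"      # encoder activation
    g: str = "identity"  # decoder activation

    def encode(self, x: np.ndarray) -> np.ndarray:
        return _ACTIVATIONS[self.f](x @ self.W_e + self.b_e)


def init_embeddings(cardinalities: list[int], dim: int, seed: int,
                    names: list[str] | None = None) -> ColumnEmbedding:
    """Seeded random initialisation, N(0, 1/sqrt(D))."""
    rng = np.random.default_rng(seed)
    scale = dim ** -0.5
    matrices = [rng.normal(0.0, scale, size=(card, dim))
                for card in cardinalities]
    names = names or [f"col_{j}" for j in range(len(cardinalities))]
    return ColumnEmbedding(matrices=matrices, column_names=names, dim=dim)


def lookup(col_index: int, code: int, embeddings: ColumnEmbedding) -> np.ndarray:
    """Embedding vector of one category: ``e_i = E[j]`` for its table."""
    table = embeddings.matrices[col_index]
    if not 0 <= code < table.shape[0]:
        name = embeddings.column_names[col_index]
        raise IndexError(
            f"code {code} out of range for column {name!r} "
            f"(cardinality {table.shape[0]})")
    return table[code]


def autoencoder_forward(x: np.ndarray, params: AutoencoderParams
                        ) -> tuple[np.ndarray, np.ndarray]:
    """One pass through encoder and decoder: returns ``(h, x_hat)``."""
    x = np.asarray(x, dtype=np.float64)
    if x.shape[-1] != params.W_e.shape[0]:
        raise ValueError(
            f"input dim {x.shape[-1]} does not match encoder dim "
            f"{params.W_e.shape[0]}")
    h = _ACTIVATIONS[params.f](x @ params.W_e + params.b_e)
    x_hat = _ACTIVATIONS[params.g](h @ params.W_d + params.b_d)
    return h, x_hat


def reconstruction_loss(batch_x: np.ndarray, batch_x_hat: np.ndarray) -> float:
    """Mean over samples of the squared reconstruction error norm."""
    x = np.atleast_2d(np.asarray(batch_x, dtype=np.float64))
    xh = np.atleast_2d(np.asarray(batch_x_hat, dtype=np.float64))
    if x.shape != xh.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {xh.shape}")
    if x.size == 0:
        raise ValueError("empty batch")
    return float(((x - xh) ** 2).sum(axis=1).mean())


def one_hot_matrix(dataset: EncodedDataset) -> np.ndarray:
    """Concatenated per-column one-hot codes, (n, sum of cardinalities)."""
    blocks = []
    for j, card in enumerate(dataset.cat_cardinalities):
        block = np.zeros((dataset.n_rows, card))
        block[np.arange(dataset.n_rows), dataset.cat_codes[:, j]] = 1.0
        blocks.append(block)
    return np.concatenate(blocks, axis=1) if blocks else np.zeros((dataset.n_rows, 0))


def pretrain_embeddings(dataset: EncodedDataset, dim: int, epochs: int,
                        seed: int, lr: float = 0.01,
                        activation: str = "relu",
                        ) -> tuple[AutoencoderParams | None, ColumnEmbedding]:
    """Unsupervised embedding initialisation via indicator autoencoding.

    Trains a one-hidden-layer autoencoder (hidden width = embedding
    dimension) on the concatenated category indicator vectors of the
    dataset, full-batch Adam, ``epochs`` update steps.  Afterwards each
    category's embedding row is set to the encoder image of its indicator
    vector.  With ``epochs == 0`` the seeded random initialisation is
    returned untouched (pre-training disabled).
    """
    if dataset.n_rows == 0:
        raise ValueError("cannot pre-train on an empty dataset")
    cards = dataset.cat_cardinalities
    embeddings = init_embeddings(cards, dim, seed, names=list(dataset.cat_names))
    if epochs == 0 or not cards:
        return None, embeddings

    X = one_hot_matrix(dataset)
    m = X.shape[1]
    rng = np.random.default_rng(seed)
    bound_e = np.sqrt(6.0 / (m + dim))
    bound_d = np.sqrt(6.0 / (dim + m))
    params = {
        "W_e": Tensor(rng.uniform(-bound_e, bound_e, size=(m, dim)),
                      requires_grad=True),
        "b_e": Tensor(np.zeros(dim), requires_grad=True),
        "W_d": Tensor(rng.uniform(-bound_d, bound_d, size=(dim, m)),
                      requires_grad=True),
        "b_d": Tensor(np.zeros(m), requires_grad=True),
    }
    act = {"relu": relu, "identity": lambda t: t}[activation]
    opt = Adam(params, lr=lr)
    Xt = Tensor(X)
    for step in range(epochs):
        h = act(matmul(Xt, params["W_e"]) + params["b_e"])
        x_hat = matmul(h, params["W_d"]) + params["b_d"]
        residual = Xt - x_hat
        loss = tmean(tsum(ad.mul(residual, residual), axis=1))
        if not np.isfinite(loss.item()):
            raise FloatingPointError(
                f"autoencoder loss diverged at step {step}: {loss.item()}")
        opt.zero_grad()
        loss.backward()
        opt.step()

    ae = AutoencoderParams(W_e=params["W_e"].data.copy(),
                           b_e=params["b_e"].data.copy(),
                           W_d=params["W_d"].data.copy(),
                           b_d=params["b_d"].data.copy(),
                           f=activation)
    offset = 0
    for j, card in enumerate(cards):
        rows = np.eye(card, m, k=offset)        # indicator vectors e_j
        embeddings.matrices[j] = ae.encode(rows)
        offset += card
    return ae, embeddings
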