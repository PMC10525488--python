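"""Hierarchical region-to-global EEG emotion classifier.

Architecture
------------
For each of the nine scalp regions r, two parallel stream encoders process the
region's band-power features:

* the *spatial* stream reads the channel sequence ``H[r]`` (one band-power
  vector per electrode) and learns inter-channel structure;
* the *temporal* stream reads the time sequence ``U[r]`` (one vector per 1 s
  segment) and learns the trial's temporal dynamics.

Each stream is a 2BGRUA encoder: two stacked bidirectional GRU layers followed
by single-head scaled dot-product self-attention, mean-pooled over sequence
positions into a fixed-length vector.  The spatial and temporal outputs are
concatenated into the region vector ``L_r`` (length ``2*d_gc + 2*d_gs``), the
nine region vectors form a 9-token sequence, and a single-layer bidirectional
GRU plus self-attention encodes it into the global feature ``G`` (length
``2*d_g``), which a softmax layer maps to class probabilities.

GRU convention (pinned for reproducibility): update gate
``z = sigmoid(x Wz + h Uz + bz)``, reset gate ``r = sigmoid(x Wr + h Ur + br)``,
candidate ``h~ = tanh(x Wh + (r*h) Uh + bh)``, new state
``h' = (1 - z) * h + z * h~``, initial state zero.  Attention uses one Q/K/V
triple of square projections per block, scores scaled by ``1/sqrt(d_K)``.

All tensors carry a leading batch axis; parameters live in a nested dict tree
of :class:`~eegemo.autodiff.Tensor` leaves, fully determined by
:class:`ModelConfig`.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .autodiff import Tensor, concat, parameter, stack
from .features import EncoderInputs
from .montage import REGION_IDS


class ModelError(ValueError):
    pass


@dataclass
class ModelConfig:
    """Hyperparameters of the hierarchical classifier.

    ``d`` is the per-position input dimension (number of frequency bands);
    ``d_hc``/``d_hs`` the first-layer BGRU hidden sizes of the channel and
    time streams; ``d_gc``/``d_gs`` the second-layer sizes; ``d_g`` the global
    BGRU hidden size; ``c`` the number of emotion classes; ``lambda_reg`` the
    L2 coefficient of the training loss.  ``shared_regions`` makes all nine
    regions share one encoder parameter set (default: per-region parameters).
    """

    d: int = 4
    d_hc: int = 64
    d_hs: int = 64
    d_gc: int = 32
    d_gs: int = 32
    d_g: int = 64
    c: int = 2
    lambda_reg: float = 1e-4
    seed: int = 0
    shared_regions: bool = False

    def __post_init__(self) -> None:
        for name in ("d", "d_hc", "d_hs", "d_gc", "d_gs", "d_g"):
            if getattr(self, name) < 1:
                raise ModelError(f"{name} must be a positive integer")
        if self.c < 2:
            raise ModelError("need at least 2 classes")
        if self.lambda_reg < 0:
            raise ModelError("lambda_reg must be non-negative")

    @property
    def region_vector_dim(self) -> int:
        return 2 * self.d_gc + 2 * self.d_gs


# ---------------------------------------------------------------------------
# parameter construction
# ---------------------------------------------------------------------------


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def _gru_direction(rng: np.random.Generator, d_in: int, d_h: int) -> dict:
    p = {}
    for gate in ("z", "r", "h"):
        p[f"W{gate}"] = parameter(_glorot(rng, d_in, d_h))
        p[f"U{gate}"] = parameter(_glorot(rng, d_h, d_h))
        p[f"b{gate}"] = parameter(np.zeros(d_h))
    return p


def make_gru_layer(rng: np.random.Generator, d_in: int, d_h: int) -> dict:
    """Bidirectional GRU layer parameters: forward + backward direction."""
    return {
        "fwd": _gru_direction(rng, d_in, d_h),
        "bwd": _gru_direction(rng, d_in, d_h),
        "hidden": d_h,
    }


def make_attention(rng: np.random.Generator, d_model: int) -> dict:
    return {
        "W_Q": parameter(_glorot(rng, d_model, d_model)),
        "W_K": parameter(_glorot(rng, d_model, d_model)),
        "W_V": parameter(_glorot(rng, d_model, d_model)),
    }


def _stream(rng: np.random.Generator, d_in: int, h1: int, h2: int) -> dict:
    return {
        "layer1": make_gru_layer(rng, d_in, h1),
        "layer2": make_gru_layer(rng, 2 * h1, h2),
        "attention": make_attention(rng, 2 * h2),
    }


def init_params(config: ModelConfig) -> dict:
    """Build the full parameter tree, deterministically from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    params: dict = {"regions": {}}
    region_ids = ("shared",) if config.shared_regions else REGION_IDS
    for rid in region_ids:
        params["regions"][rid] = {
            "spatial": _stream(rng, config.d, config.d_hc, config.d_gc),
            "temporal": _stream(rng, config.d, config.d_hs, config.d_gs),
        }
    params["global"] = {
        "bgru": make_gru_layer(rng, config.region_vector_dim, config.d_g),
        "attention": make_attention(rng, 2 * config.d_g),
    }
    params["classifier"] = {
        "W_z": parameter(_glorot(rng, 2 * config.d_g, config.c)),
        "b_z": parameter(np.zeros(config.c)),
    }
    return params


def iter_parameters(tree) -> list[Tensor]:
    """All Tensor leaves of a parameter tree, in deterministic order."""
    out: list[Tensor] = []
    if isinstance(tree, Tensor):
        out.append(tree)
    elif isinstance(tree, Mapping):
        for key in tree:
            out.extend(iter_parameters(tree[key]))
    return out


def n_parameters(tree) -> int:
    return sum(p.data.size for p in iter_parameters(tree))


# ---------------------------------------------------------------------------
# forward computation
# ---------------------------------------------------------------------------


def gru_step(x: Tensor, h_prev: Tensor, direction: Mapping) -> Tensor:
    """One GRU update for a (possibly batched) input ``x`` and state ``h_prev``."""
    if x.shape[-1] != direction["Wz"].shape[0]:
        raise ModelError(
            f"input dim {x.shape[-1]} does not match GRU input "
            f"dim {direction['Wz'].shape[0]}"
        )
    z = (x @ direction["Wz"] + h_prev @ direction["Uz"] + direction["bz"]).sigmoid()
    r = (x @ direction["Wr"] + h_prev @ direction["Ur"] + direction["br"]).sigmoid()
    h_cand = (x @ direction["Wh"] + (r * h_prev) @ direction["Uh"] + direction["bh"]).tanh()
    return (1.0 - z) * h_prev + z * h_cand


def _run_direction(xs: list[Tensor], direction: Mapping, d_h: int) -> list[Tensor]:
    batch_shape = xs[0].shape[:-1]
    h = Tensor(np.zeros(batch_shape + (d_h,)))
    out = []
    for x in xs:
        h = gru_step(x, h, direction)
        out.append(h)
    return out


def bgru(seq: Tensor, layer: Mapping) -> Tensor:
    """Bidirectional GRU over ``seq`` of shape (..., n, d_in) -> (..., n, 2*h).

    Position t of the output concatenates the forward state after reading
    positions 1..t and the backward state after reading positions n..t.
    """
    n = seq.shape[-2]
    if n < 1:
        raise ModelError("bgru requires a non-empty sequence")
    xs = [seq[..., t, :] for t in range(n)]
    d_h = layer["hidden"]
    fwd = _run_direction(xs, layer["fwd"], d_h)
    bwd = _run_direction(xs[::-1], layer["bwd"], d_h)[::-1]
    return stack([concat([f, b], axis=-1) for f, b in zip(fwd, bwd)], axis=-2)


def self_attention(x: Tensor, attn: Mapping) -> Tensor:
    """Single-head scaled dot-product self-attention over (..., n, d_model).

    ``softmax(Q K^T / sqrt(d_K)) V`` with Q, K, V square linear projections of
    the input; attention rows are a probability distribution over positions.
    """
    if x.shape[-1] != attn["W_Q"].shape[0]:
        raise ModelError(
            f"model dim {x.shape[-1]} does not match attention dim "
            f"{attn['W_Q'].shape[0]}"
        )
    q = x @ attn["W_Q"]
    k = x @ attn["W_K"]
    v = x @ attn["W_V"]
    d_k = k.shape[-1]
    scores = (q @ k.swap_last_axes()) * (1.0 / np.sqrt(d_k))
    return scores.softmax(axis=-1) @ v


def attention_weights(x: np.ndarray, attn: Mapping) -> np.ndarray:
    """The row-stochastic attention matrix itself (for inspection/tests)."""
    q = x @ attn["W_Q"].data
    k = x @ attn["W_K"].data
    scores = (q @ np.swapaxes(k, -1, -2)) / np.sqrt(k.shape[-1])
    shifted = scores - scores.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)


def stream_encode_2bgrua(seq: Tensor, stream: Mapping) -> Tensor:
    """2BGRUA stream encoder: BGRU -> BGRU -> self-attention -> mean pool.

    ``seq`` has shape (..., n, d); the result (..., 2*layer2_hidden) is
    independent of the sequence length n because attention outputs are
    mean-pooled over positions.
    """
    h1 = bgru(seq, stream["layer1"])
    h2 = bgru(h1, stream["layer2"])
    att = self_attention(h2, stream["attention"])
    return att.mean(axis=-2)


def regional_encode(H_r: Tensor, U_r: Tensor, region: Mapping) -> Tensor:
    """Fuse one region's spatial and temporal stream outputs into ``L_r``.

    ``H_r``: (..., N_r, d) channel sequence; ``U_r``: (..., T, d) time
    sequence.  Output concatenates (spatial, temporal) in that order.
    """
    s = stream_encode_2bgrua(H_r, region["spatial"])
    t = stream_encode_2bgrua(U_r, region["temporal"])
    return concat([s, t], axis=-1)


def global_encode(region_vectors: Sequence[Tensor], global_params: Mapping) -> Tensor:
    """Encode the nine region vectors into the global feature ``G``.

    The region vectors form a 9-token sequence; a single bidirectional GRU
    layer yields the 9 hidden states of dimension ``2*d_g``, self-attention
    re-weights them, and mean pooling gives ``G``.
    """
    if len(region_vectors) != len(REGION_IDS):
        raise ModelError(
            f"global encoder expects {len(REGION_IDS)} region vectors, "
            f"got {len(region_vectors)}"
        )
    tokens = stack(list(region_vectors), axis=-2)
    e = bgru(tokens, global_params["bgru"])
    att = self_attention(e, global_params["attention"])
    return att.mean(axis=-2)


def classify(g: Tensor, w_z: Tensor, b_z: Tensor) -> Tensor:
    """Softmax class probabilities from the global feature ``G``."""
    logits = g @ w_z + b_z
    return logits.softmax(axis=-1)


def _region_params(params: Mapping, rid: str) -> Mapping:
    regions = params["regions"]
    return regions["shared"] if "shared" in regions else regions[rid]


def forward_batch(
    H: Mapping[str, np.ndarray], U: Mapping[str, np.ndarray], params: Mapping
) -> Tensor:
    """Class probabilities for a batch.

    ``H[rid]`` has shape (B, d, N_r) and ``U[rid]`` shape (B, d, T) — the
    natural feature-tensor orientation; they are transposed internally so the
    sequence axis comes before the feature axis.
    """
    region_vecs = []
    for rid in REGION_IDS:
        h_seq = Tensor(np.swapaxes(np.asarray(H[rid], dtype=float), -1, -2))
        u_seq = Tensor(np.swapaxes(np.asarray(U[rid], dtype=float), -1, -2))
        region_vecs.append(regional_encode(h_seq, u_seq, _region_params(params, rid)))
    g = global_encode(region_vecs, params["global"])
    return classify(g, params["classifier"]["W_z"], params["classifier"]["b_z"])


def forward(inputs: EncoderInputs, params: Mapping) -> tuple[np.ndarray, int]:
    """Predict one trial: returns (probability vector, class index).

    Ties in the argmax resolve to the lowest class index.
    """
    missing = [rid for rid in REGION_IDS if rid not in inputs.H]
    if missing:
        raise ModelError(f"missing regions in encoder inputs: {missing}")
    H = {rid: inputs.H[rid][None] for rid in REGION_IDS}
    U = {rid: inputs.U[rid][None] for rid in REGION_IDS}
    probs = forward_batch(H, U, params).data[0]
    return probs, int(np.argmax(probs))


def predict_batch(
    H: Mapping[str, np.ndarray], U: Mapping[str, np.ndarray], params: Mapping
) -> tuple[np.ndarray, np.ndarray]:
    """Probabilities (B, c) and predicted class indices (B,) for a batch."""
    probs = forward_batch(H, U, params).data
    return probs, probs.argmax(axis=-1)


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------


def _flatten(tree, prefix: str = "") -> dict[str, np.ndarray]:
    flat: dict[str, np.ndarray] = {}
    if isinstance(tree, Tensor):
        flat[prefix.rstrip("/")] = tree.data
    elif isinstance(tree, Mapping):
        for key, sub in tree.items():
            if key == "hidden":
                continue
            flat.update(_flatten(sub, f"{prefix}{key}/"))
    return flat


def save_checkpoint(path: str | Path, params: Mapping, config: ModelConfig) -> None:
    """Write the parameter tree + config to a single ``.npz`` container."""
    flat = _flatten(params)
    np.savez(
        path, __config__=np.frombuffer(json.dumps(asdict(config)).encode(), dtype=np.uint8), **flat
    )


def load_checkpoint(path: str | Path) -> tuple[dict, ModelConfig]:
    """Round-trip counterpart of :func:`save_checkpoint` (bit-exact)."""
    with np.load(path) as archive:
        config = ModelConfig(**json.loads(bytes(archive["__config__"]).decode()))
        params = init_params(config)
        flat = _flatten(params)
        for key, leaf in flat.items():
            leaf[...] = archive[key]
    return params, config
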