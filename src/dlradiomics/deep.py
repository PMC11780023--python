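"""Fixed-length 2-D crop embeddings via pluggable backends.

Two weight modes exist:

* ``pretrained`` — loads the torchvision architecture and reads its
  penultimate-layer activations.  Requires torch/torchvision; if they are
  not installed an explicit error points at the alternatives.
* ``random`` (default) — a deterministic seeded filterbank embedding with
  the architecture's penultimate dimension and input size: a bank of
  random convolution kernels, ReLU, spatial average pooling over a coarse
  grid, then a seeded random projection.  It is a frozen, reproducible
  feature extractor with no download; it preserves image content (it is
  non-constant on non-constant images) but carries no ImageNet prior.

The ``pseudo`` backend is the same filterbank with a configurable
dimension, intended for tests and fast end-to-end runs.

Each of the five per-phase slice embeddings is aggregated to one
case-level vector by the element-wise mean (permutation invariant).
"""

from __future__ import annotations

import dataclasses
import functools
import hashlib

import numpy as np
import pandas as pd
from scipy import signal
from skimage.transform import resize

from .slices import SliceStack

__all__ = ["BackendSpec", "EmbeddingVector", "embed_slice", "aggregate_case", "embed_cohort"]

# penultimate-layer widths and input sizes of the supported architectures
BACKEND_DIMS = {"vit": 1024, "vgg19": 4096, "googlenet": 1024, "inception_v3": 2048}
BACKEND_INPUT = {
    "vit": (224, 224),
    "vgg19": (224, 224),
    "googlenet": (224, 224),
    "inception_v3": (299, 299),
    "pseudo": (64, 64),
}
# fixed channel standardisation constants (recorded for reproducibility)
CHANNEL_MEAN = (0.485, 0.456, 0.406)
CHANNEL_STD = (0.229, 0.224, 0.225)


@dataclasses.dataclass(frozen=True)
class BackendSpec:
    """Embedding backend contract: name fixes dimension and input size."""

    name: str = "pseudo"
    weights: str = "random"  # "pretrained" | "random"
    embed_dim: int | None = None  # configurable for pseudo only
    seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in BACKEND_INPUT:
            raise ValueError(
                f"unknown backend {self.name!r}; choose from {sorted(BACKEND_INPUT)}"
            )
        if self.weights not in ("pretrained", "random"):
            raise ValueError("weights must be 'pretrained' or 'random'")
        if self.name == "pseudo":
            dim = self.embed_dim if self.embed_dim is not None else 64
            object.__setattr__(self, "embed_dim", int(dim))
        else:
            expected = BACKEND_DIMS[self.name]
            if self.embed_dim is not None and self.embed_dim != expected:
                raise ValueError(
                    f"{self.name} penultimate dimension is fixed at {expected}"
                )
            object.__setattr__(self, "embed_dim", expected)

    @property
    def input_size(self) -> tuple[int, int]:
        return BACKEND_INPUT[self.name]


@dataclasses.dataclass(frozen=True)
class EmbeddingVector:
    case_id: str
    phase: str
    backend: str
    values: np.ndarray


def _standardize(image: np.ndarray, size: tuple[int, int]) -> np.ndarray:
    """Resize (bilinear), min-max to [0,1], fixed channel standardisation.

    Channels are identical replicas, so the standardised stack is averaged
    back to one plane for the filterbank path.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.size == 0:
        raise ValueError("empty image")
    img = resize(img, size, order=1, mode="edge", anti_aliasing=False)
    rng_ = img.max() - img.min()
    img = (img - img.min()) / rng_ if rng_ > 0 else np.zeros_like(img)
    chans = [(img - m) / s for m, s in zip(CHANNEL_MEAN, CHANNEL_STD)]
    return np.mean(chans, axis=0)


def _filterbank_seed(spec: BackendSpec) -> int:
    if spec.name == "pseudo":
        return spec.seed
    # named backends with random weights: stable per-architecture seed
    h = hashlib.sha256(f"{spec.name}:{spec.seed}".encode()).digest()
    return int.from_bytes(h[:4], "big")


_N_KERNELS = 16
_KERNEL_SIZE = 7
_POOL_GRID = 4


@functools.lru_cache(maxsize=8)
def _filterbank(spec: BackendSpec):
    rng = np.random.default_rng(_filterbank_seed(spec))
    kernels = rng.standard_normal((_N_KERNELS, _KERNEL_SIZE, _KERNEL_SIZE))
    kernels -= kernels.mean(axis=(1, 2), keepdims=True)
    n_stats = _N_KERNELS * (_POOL_GRID * _POOL_GRID + 2)
    proj = rng.standard_normal((spec.embed_dim, n_stats)) / np.sqrt(n_stats)
    bias = rng.standard_normal(spec.embed_dim) * 0.1
    return kernels, proj, bias


def _filterbank_embed(image: np.ndarray, spec: BackendSpec) -> np.ndarray:
    x = _standardize(image, spec.input_size)
    kernels, proj, bias = _filterbank(spec)
    stats = []
    h, w = x.shape
    gh, gw = h // _POOL_GRID, w // _POOL_GRID
    for k in kernels:
        fm = np.maximum(signal.fftconvolve(x, k, mode="same"), 0.0)
        pooled = (
            fm[: gh * _POOL_GRID, : gw * _POOL_GRID]
            .reshape(_POOL_GRID, gh, _POOL_GRID, gw)
            .mean(axis=(1, 3))
        )
        stats.append(np.concatenate([pooled.ravel(), [fm.max(), fm.std()]]))
    stats = np.concatenate(stats)
    return np.tanh(proj @ stats + bias)


def _torch_embed(image: np.ndarray, spec: BackendSpec) -> np.ndarray:
    try:
        import torch  # noqa: F401
        import torchvision  # noqa: F401
    except ImportError as err:
        raise RuntimeError(
            f"backend {spec.name!r} with pretrained weights requires torch/"
            "torchvision, which are not installed; use weights='random' for "
            "an architecture-dimension-faithful seeded filterbank, or the "
            "'pseudo' backend for tests"
        ) from err
    raise NotImplementedError(
        "pretrained torchvision extraction is only available when torch is "
        "installed; this build ships the seeded filterbank backends"
    )


def embed_slice(image: np.ndarray, backend: BackendSpec) -> np.ndarray:
    """Embed one 2-D crop; returns exactly ``backend.embed_dim`` reals."""
    if backend.weights == "pretrained":
        return _torch_embed(image, backend)
    out = _filterbank_embed(image, backend)
    assert out.shape == (backend.embed_dim,) and np.all(np.isfinite(out))
    return out


def aggregate_case(slice_vectors: list[np.ndarray]) -> np.ndarray:
    """Element-wise mean of the five slice embeddings (order-invariant)."""
    if len(slice_vectors) != 5:
        raise ValueError(f"expected 5 slice vectors, got {len(slice_vectors)}")
    arr = np.asarray(slice_vectors, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError("slice vectors must share one length")
    return arr.mean(axis=0)


def embed_stack(stack: SliceStack, backend: BackendSpec) -> EmbeddingVector:
    vecs = [embed_slice(img, backend) for img in stack.images]
    return EmbeddingVector(stack.case_id, stack.phase, backend.name, aggregate_case(vecs))


def embed_cohort(stacks: list[SliceStack], backend: BackendSpec) -> pd.DataFrame:
    """Case-by-feature table per phase; columns '{phase}_{backend}_{i:04d}'."""
    rows: dict[str, dict[str, float]] = {}
    for st in stacks:
        ev = embed_stack(st, backend)
        row = rows.setdefault(st.case_id, {})
        row.update(
            {
                f"{st.phase}_{backend.name}_{i:04d}": v
                for i, v in enumerate(ev.values)
            }
        )
    table = pd.DataFrame.from_dict(rows, orient="index").sort_index(axis=1)
    table.index.name = "case_id"
    if table.isna().any().any():
        raise ValueError("missing embeddings for some case-phase pairs")
    return table
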