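"""Spectrogram-to-vector embedding behind a pluggable contract.

Every normalized Mel spectrogram is rendered as a 3-channel image and
mapped to a fixed-length vector of 1000 raw class scores ("logits", no
softmax anywhere).  Downstream code depends only on the contract (a
deterministic callable with a fixed output dimension), never on which
embedder produced the vectors:

* :class:`FixtureEmbedder` — a deterministic seeded random-projection
  embedder over 16x16 image patches; the default, dependency-free path.
* :func:`vit_embed` — an optional plug-in for a real pretrained
  16x16-patch, 1000-class Vision Transformer (requires torch + timm and
  locally available weights; never used by the test suite).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .io import VALVES
from .spectrogram import MelSpec

__all__ = [
    "EmbeddingArray",
    "FixtureEmbedder",
    "spec_to_image",
    "fixture_embed",
    "vit_embed",
    "build_embedding_array",
]

DEFAULT_DIM = 1000
DEFAULT_IMAGE_SIZE = 224
PATCH = 16


@dataclass
class EmbeddingArray:
    """The (groups x 4 channels x dim) feature tensor with aligned labels."""

    values: np.ndarray
    group_ids: list
    labels: np.ndarray
    patient_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.values.ndim != 3:
            raise ValueError("embedding values must be (groups, channels, dim)")
        if not (self.values.shape[0] == len(self.group_ids) == len(self.labels)):
            raise ValueError("group_ids/labels must align with the first axis")

    @property
    def dim(self) -> int:
        return self.values.shape[2]

    def permuted(self, order: np.ndarray) -> "EmbeddingArray":
        """Jointly permute values, ids, and labels (alignment preserved)."""
        return EmbeddingArray(
            values=self.values[order],
            group_ids=[self.group_ids[i] for i in order],
            labels=self.labels[order],
            patient_ids=[self.patient_ids[i] for i in order] if self.patient_ids else [],
        )


def spec_to_image(spec: MelSpec, size: int = DEFAULT_IMAGE_SIZE) -> np.ndarray:
    """Bilinear-resize a normalized spectrogram to (size, size, 3) in [0, 1]."""
    m = spec.matrix
    if m.size == 0:
        raise ValueError("empty spectrogram")
    if not spec.normalized:
        raise ValueError("spectrogram must be normalized before imaging")
    zoomed = ndimage.zoom(m, (size / m.shape[0], size / m.shape[1]), order=1,
                          mode="nearest", grid_mode=True)
    zoomed = np.clip(zoomed[:size, :size], 0.0, 1.0)
    return np.repeat(zoomed[:, :, None], 3, axis=2)


class FixtureEmbedder:
    """Deterministic patch-projection embedder with the logit contract.

    The image is split into 16x16 patches; each flattened patch gets a
    fixed seeded positional encoding added (patch identity matters, as
    in a transformer), is projected by a fixed seeded Gaussian matrix
    and squashed (tanh).  Patch codes are then mean-pooled along the
    image's horizontal (time) axis only — the vertical axis of a
    spectrogram image is frequency, whose profile carries the signal's
    spectral signature — and the per-row codes are flattened and
    projected to ``dim`` raw scores.  A pure function of (image, seed):
    the same image always embeds to the same vector, and changing any
    one patch changes the output.
    """

    def __init__(self, dim: int = DEFAULT_DIM, seed: int = 0, hidden: int = 64,
                 input_size: int = DEFAULT_IMAGE_SIZE):
        if input_size % PATCH:
            raise ValueError(f"input_size must be a multiple of {PATCH}")
        self.name = "fixture"
        self.dim = dim
        self.seed = seed
        self.input_size = input_size
        self.deterministic = True
        self._grid = input_size // PATCH
        rng = np.random.default_rng(seed)
        n_in = PATCH * PATCH * 3
        self._pos = 0.5 * rng.standard_normal((self._grid * self._grid, n_in))
        self._w1 = rng.standard_normal((n_in, hidden)) / np.sqrt(n_in)
        self._w2 = rng.standard_normal((self._grid * hidden, dim)) / np.sqrt(self._grid * hidden)

    def _patches(self, image: np.ndarray) -> np.ndarray:
        h, w, c = image.shape
        if (h, w) != (self.input_size, self.input_size):
            raise ValueError(f"expected a {self.input_size}x{self.input_size} image")
        p = image.reshape(h // PATCH, PATCH, w // PATCH, PATCH, c)
        return p.transpose(0, 2, 1, 3, 4).reshape(-1, PATCH * PATCH * c)

    def __call__(self, image: np.ndarray) -> np.ndarray:
        codes = np.tanh((self._patches(image) + self._pos) @ self._w1)
        hidden = codes.shape[1]
        row_codes = codes.reshape(self._grid, self._grid, hidden).mean(axis=1)
        return row_codes.ravel() @ self._w2


def fixture_embed(image: np.ndarray, seed: int = 0, dim: int = DEFAULT_DIM) -> np.ndarray:
    """Functional one-shot wrapper around :class:`FixtureEmbedder`."""
    return FixtureEmbedder(dim=dim, seed=seed)(image)


def vit_embed(image: np.ndarray, model_name: str = "vit_base_patch16_224"):
    """Class scores from a locally available pretrained Vision Transformer.

    Optional plug-in; raises with guidance when torch/timm or weights are
    unavailable.  Returns the raw 1000-dim logit vector (no softmax).
    """
    try:
        import timm
        import torch
    except ImportError as exc:
        raise ImportError(
            "vit_embed needs the optional 'vit' extra (torch + timm) and local "
            "pretrained weights; use the default FixtureEmbedder otherwise"
        ) from exc
    model = timm.create_model(model_name, pretrained=True)
    model.eval()
    x = torch.from_numpy(np.ascontiguousarray(image.transpose(2, 0, 1))[None]).float()
    with torch.no_grad():
        logits = model(x)
    return logits.numpy()[0]


def build_embedding_array(groups, embedder, size: int = DEFAULT_IMAGE_SIZE) -> EmbeddingArray:
    """Embed labeled 4-spectrogram groups into a (n, 4, dim) tensor.

    ``groups`` is an iterable of (group_id, {valve: MelSpec}, label) or
    (group_id, {valve: MelSpec}, label, patient_id) tuples; each group
    must have exactly the four valve channels.  Label alignment is by
    index and survives any later joint permutation.
    """
    values, group_ids, labels, patient_ids = [], [], [], []
    for item in groups:
        gid, specs, label = item[0], item[1], item[2]
        pid = item[3] if len(item) > 3 else str(gid).split(":")[0]
        if set(specs) != set(VALVES):
            raise ValueError(f"group {gid}: expected 4 valve channels, got {sorted(specs)}")
        vecs = [embedder(spec_to_image(specs[v], size)) for v in VALVES]
        values.append(np.stack(vecs).astype(np.float32))
        group_ids.append(gid)
        labels.append(label)
        patient_ids.append(pid)
    if not values:
        return EmbeddingArray(
            values=np.empty((0, 4, embedder.dim), dtype=np.float32),
            group_ids=[], labels=np.empty((0,), dtype=object), patient_ids=[],
        )
    return EmbeddingArray(
        values=np.stack(values), group_ids=group_ids,
        labels=np.asarray(labels), patient_ids=patient_ids,
    )
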