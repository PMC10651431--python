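"""Backbone contract: per-token sequence representations.

A backbone maps an amino-acid sequence of length N to an (N+2) x D matrix:
row 0 is the CLS (whole-sequence) token, rows 1..N are the residues, row
N+1 is the END token.  Two implementations are provided:

* :class:`MockBackbone` — a deterministic, CPU-only stand-in whose rows are
  seeded functions of (residue, position); it makes head and training
  behaviour exactly testable without a language model.
* :class:`EsmBackbone` — an adapter for a real protein language model
  (``fair-esm``), importable only where that optional dependency exists.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import AA_SET


@dataclass
class EmbeddingMatrix:
    """(N+2) x D representation of a length-N sequence.

    Row 0 = CLS, rows 1..N = residues, row N+1 = END.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] < 3:
            raise ValueError(f"embedding must be (N+2) x D with N >= 1, got {v.shape}")
        if not np.isfinite(v).all():
            raise ValueError("embedding contains non-finite entries")
        self.values = v

    @property
    def n_residues(self) -> int:
        return self.values.shape[0] - 2

    @property
    def width(self) -> int:
        return self.values.shape[1]

    @property
    def cls_row(self) -> np.ndarray:
        return self.values[0]


def mutation_row(embedding: EmbeddingMatrix, position: int) -> np.ndarray:
    """Residue row for a 0-based sequence position (the +1 CLS shift is
    internal to this function; callers never see it)."""
    if not 0 <= position < embedding.n_residues:
        raise IndexError(
            f"position {position} outside sequence of length {embedding.n_residues}")
    return embedding.values[position + 1]


@dataclass
class BackboneSpec:
    name: str
    width: int
    trainable: bool
    max_length: int

    def __post_init__(self) -> None:
        if self.width < 1:
            raise ValueError("embedding width must be >= 1")


class SequenceError(ValueError):
    """Illegal character or disallowed length in an input sequence."""


def _validate_sequence(sequence: str, max_length: int) -> None:
    if len(sequence) == 0:
        raise SequenceError("empty sequence: no residues to embed")
    if len(sequence) > max_length:
        raise SequenceError(
            f"sequence of length {len(sequence)} exceeds backbone maximum {max_length}")
    for i, aa in enumerate(sequence):
        if aa not in AA_SET:
            raise SequenceError(f"illegal character {aa!r} at position {i}")


class MockBackbone:
    """Deterministic per-token embedder for CPU-only tests.

    Row i of the residue block is a pure function of (seed, position i, the
    residues within ``locality_window`` of i), drawn as scaled standard
    normals from a counter-based generator, so the same sequence always
    yields the bitwise-identical matrix and a single-residue change alters
    exactly the rows within the window plus the CLS row (the CLS row is the
    mean of all residue rows).  The END row depends only on (seed, length).

    When ``trainable`` is true the raw matrix is passed through an
    identity-initialised linear projection (weight ``proj``, bias ``bias``)
    whose parameters receive gradients during end-to-end training; with the
    projection at its initial value the output equals the raw embedding.
    """

    def __init__(self, width: int = 16, seed: int = 0, max_length: int = 2048,
                 locality_window: int = 0, trainable: bool = True) -> None:
        if width < 1:
            raise ValueError("width must be >= 1")
        self.width = width
        self.seed = int(seed)
        self.max_length = max_length
        self.locality_window = int(locality_window)
        self.trainable = trainable
        self.proj = np.eye(width)
        self.bias = np.zeros(width)

    @property
    def spec(self) -> BackboneSpec:
        return BackboneSpec(name="mock", width=self.width,
                            trainable=self.trainable, max_length=self.max_length)

    # raw (pre-projection) rows -------------------------------------------

    def _residue_row(self, sequence: str, i: int) -> np.ndarray:
        w = self.locality_window
        lo, hi = max(0, i - w), min(len(sequence), i + w + 1)
        context = [ord(c) for c in sequence[lo:hi]]
        rng = np.random.default_rng([self.seed, 1, i] + context)
        return rng.standard_normal(self.width) / np.sqrt(self.width)

    def raw_embed(self, sequence: str) -> np.ndarray:
        _validate_sequence(sequence, self.max_length)
        n = len(sequence)
        rows = np.empty((n + 2, self.width))
        for i in range(n):
            rows[i + 1] = self._residue_row(sequence, i)
        rows[0] = rows[1:n + 1].mean(axis=0)  # CLS tracks every residue
        end_rng = np.random.default_rng([self.seed, 2, n])
        rows[n + 1] = end_rng.standard_normal(self.width) / np.sqrt(self.width)
        return rows

    def embed(self, sequence: str) -> EmbeddingMatrix:
        raw = self.raw_embed(sequence)
        if self.trainable:
            raw = raw @ self.proj.T + self.bias
        return EmbeddingMatrix(raw)

    # parameter interface used by the trainer -----------------------------

    def parameters(self) -> dict[str, np.ndarray]:
        return {"proj": self.proj, "bias": self.bias} if self.trainable else {}


class EsmBackbone:
    """Adapter for an ESM-family protein language model.

    Requires the optional ``fair-esm``/``torch`` stack; construction fails
    with an informative error when it is absent.  The model's beginning- and
    end-of-sequence tokens fill the CLS and END rows of the contract.
    """

    DEFAULT_MODEL = "esm2_t33_650M_UR50D"
    DEFAULT_WIDTH = 1280

    def __init__(self, model_name: str = DEFAULT_MODEL, max_length: int = 1022):
        try:
            import esm  # type: ignore
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise ImportError(
                "the real language-model backbone requires the optional "
                "'fair-esm' package (and torch); use MockBackbone for "
                "CPU-only work") from exc
        self._model, alphabet = getattr(esm.pretrained, model_name)()  # pragma: no cover
        self._converter = alphabet.get_batch_converter()  # pragma: no cover
        self.width = self._model.embed_dim  # pragma: no cover
        self.max_length = max_length  # pragma: no cover

    def embed(self, sequence: str) -> EmbeddingMatrix:  # pragma: no cover
        import torch  # type: ignore

        _validate_sequence(sequence, self.max_length)
        _, _, toks = self._converter([("seq", sequence)])
        with torch.no_grad():
            out = self._model(toks, repr_layers=[self._model.num_layers])
        reps = out["representations"][self._model.num_layers][0]
        return EmbeddingMatrix(reps[: len(sequence) + 2].numpy())

    def parameters(self) -> dict:  # pragma: no cover
        return {}


def embed(sequence: str, backbone) -> EmbeddingMatrix:
    """Embed a sequence with any backbone implementing the contract."""
    return backbone.embed(sequence)


def make_backbone(config: dict):
    """Build a backbone from a config mapping, e.g.
    ``{"kind": "mock", "width": 16, "seed": 0}``."""
    kind = config.get("kind", "mock")
    if kind == "mock":
        keys = ("width", "seed", "max_length", "locality_window", "trainable")
        return MockBackbone(**{k: config[k] for k in keys if k in config})
    if kind == "esm":
        keys = ("model_name", "max_length")
        return EsmBackbone(**{k: config[k] for k in keys if k in config})
    raise ValueError(f"unknown backbone kind {kind!r}")
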