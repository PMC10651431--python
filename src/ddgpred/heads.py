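"""Siamese regression heads over a shared embedding backbone.

Five admissible combinations of (embedding source, merge) turn the
wild-type and mutant representations into one feature vector that feeds a
one-hidden-layer network predicting ddG (kcal/mol):

====================  =============  ==============
embedding source      merge          feature width
====================  =============  ==============
position              concatenation  2D
position              outer_product  D^2
position              linear         D
cls                   linear         D
cls_plus_position     linear         2D
====================  =============  ==============

The linear merge forms ``w_WT (*) e_WT + w_MT (*) e_MT`` with element-wise
products and trainable weight vectors; it is the only merge whose swap
behaviour is controlled by the weights, which is why linear-merge heads can
stay symmetric under direction reversal while outer-product and
concatenation heads cannot.

Heads are scikit-learn style estimators: hyperparameters in ``__init__``,
state learned by :meth:`fit` in trailing-underscore attributes,
:meth:`predict` on lists of :class:`~ddgpred.datamodel.VariantPair`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.exceptions import NotFittedError

from .datamodel import VariantPair
from .embedding import EmbeddingMatrix, MockBackbone, mutation_row

ADMISSIBLE_HEADS: tuple[tuple[str, str], ...] = (
    ("position", "concatenation"),
    ("position", "outer_product"),
    ("position", "linear"),
    ("cls", "linear"),
    ("cls_plus_position", "linear"),
)


@dataclass(frozen=True)
class HeadSpec:
    """One admissible (embedding source, merge) combination."""

    embedding_source: str
    merge: str
    hidden_width: int = 128

    def __post_init__(self) -> None:
        if (self.embedding_source, self.merge) not in ADMISSIBLE_HEADS:
            raise ValueError(
                f"({self.embedding_source!r}, {self.merge!r}) is not one of the "
                f"admissible head combinations {ADMISSIBLE_HEADS}")
        if self.hidden_width < 1:
            raise ValueError("hidden width must be >= 1")

    @property
    def name(self) -> str:
        return f"{self.embedding_source}-{self.merge}"

    def feature_width(self, d: int) -> int:
        if self.merge == "concatenation":
            return 2 * d
        if self.merge == "outer_product":
            return d * d
        return 2 * d if self.embedding_source == "cls_plus_position" else d

    def source_width(self, d: int) -> int:
        """Width of the per-sequence vector the merge consumes."""
        return 2 * d if self.embedding_source == "cls_plus_position" else d


def select_rows(spec: HeadSpec, embedding: EmbeddingMatrix, position: int) -> np.ndarray:
    """Per-sequence vector the head consumes: the mutation-position row, the
    CLS row, or their concatenation."""
    if spec.embedding_source == "position":
        return mutation_row(embedding, position)
    if spec.embedding_source == "cls":
        return embedding.cls_row
    return np.concatenate([embedding.cls_row, mutation_row(embedding, position)])


def combine(spec: HeadSpec, wt_embedding: EmbeddingMatrix,
            mt_embedding: EmbeddingMatrix, position: int,
            w_wt: np.ndarray | None = None, w_mt: np.ndarray | None = None,
            outer_cap: int = 256) -> np.ndarray:
    """Merge WT and MT embeddings into the head's feature vector.

    For the linear merge, ``w_wt``/``w_mt`` default to all-ones (a plain
    sum).  The outer product is materialised at full D^2 only for D up to
    ``outer_cap``.
    """
    if wt_embedding.width != mt_embedding.width:
        raise ValueError(
            f"embedding width mismatch: {wt_embedding.width} vs {mt_embedding.width}")
    e_wt = select_rows(spec, wt_embedding, position)
    e_mt = select_rows(spec, mt_embedding, position)
    if spec.merge == "concatenation":
        return np.concatenate([e_wt, e_mt])
    if spec.merge == "outer_product":
        d = e_wt.size
        if d > outer_cap:
            raise ValueError(
                f"outer-product merge at width {d} would materialise {d * d} "
                f"features (cap {outer_cap}); use a narrower backbone or raise "
                f"outer_cap explicitly")
        return np.outer(e_wt, e_mt).ravel()
    # linear merge
    if w_wt is None:
        w_wt = np.ones_like(e_wt)
    if w_mt is None:
        w_mt = np.ones_like(e_mt)
    if w_wt.shape != e_wt.shape or w_mt.shape != e_mt.shape:
        raise ValueError("linear-merge weight vectors must match the source width")
    return w_wt * e_wt + w_mt * e_mt


class HeadRegressor(BaseEstimator, RegressorMixin):
    """ddG regressor: one embedding-combination head over a backbone.

    Parameters
    ----------
    embedding_source, merge : str
        One of the five admissible combinations (see module docstring).
    hidden_width : int
        Width of the single hidden layer (tanh nonlinearity).
    antisymmetric : bool
        If true, tie ``w_MT = -w_WT`` and freeze every bias at zero, making
        the whole head an odd function of direction: ``predict(wt, mt) ==
        -predict(mt, wt)`` exactly, by construction.  Off by default — with
        reverse-augmented data the symmetry is learned rather than imposed.
    backbone : object or None
        Any object with ``embed(sequence) -> EmbeddingMatrix``; None means a
        default :class:`MockBackbone` is created at initialisation time.
    learning_rate, warmup_fraction, epochs, batch_size, seed, freeze_backbone
        Training hyperparameters; see :mod:`ddgpred.training`.
    outer_cap : int
        Largest embedding width for which the outer-product merge will
        materialise its D^2 features.

    Attributes
    ----------
    params_ : dict of str -> ndarray
        Trainable arrays (merge weights, hidden layer, output layer, and the
        backbone's own parameters unless frozen).
    loss_trace_ : ndarray
        Per-example squared-error losses in training order.
    backbone_ : object
        The backbone used for embedding.
    """

    def __init__(self, embedding_source: str = "position", merge: str = "linear",
                 hidden_width: int = 128, antisymmetric: bool = False,
                 backbone=None, learning_rate: float = 1e-5,
                 warmup_fraction: float = 0.30, epochs: int = 3,
                 batch_size: int = 1, seed: int = 0,
                 freeze_backbone: bool = False, outer_cap: int = 256):
        self.embedding_source = embedding_source
        self.merge = merge
        self.hidden_width = hidden_width
        self.antisymmetric = antisymmetric
        self.backbone = backbone
        self.learning_rate = learning_rate
        self.warmup_fraction = warmup_fraction
        self.epochs = epochs
        self.batch_size = batch_size
        self.seed = seed
        self.freeze_backbone = freeze_backbone
        self.outer_cap = outer_cap

    # ------------------------------------------------------------------
    @property
    def spec(self) -> HeadSpec:
        return HeadSpec(self.embedding_source, self.merge, self.hidden_width)

    def _check_initialized(self) -> None:
        if not hasattr(self, "params_"):
            raise NotFittedError(
                "this head has no weights yet; call fit() or initialize() — "
                "predictions from an uninitialised model would be silent noise")

    def initialize(self, backbone=None) -> "HeadRegressor":
        """Set up weights (deterministic under ``seed``) without training.

        Linear-merge weight vectors start at all-ones, so the initial merge
        is a plain sum of the two embeddings; under the antisymmetric tying
        the single weight vector starts at all-ones with ``w_MT`` implied as
        its negation.
        """
        if self.antisymmetric and self.merge != "linear":
            raise ValueError("antisymmetric tying requires the linear merge")
        spec = self.spec
        self.backbone_ = backbone if backbone is not None else (
            self.backbone if self.backbone is not None else MockBackbone(seed=self.seed))
        d = self.backbone_.width
        f = spec.feature_width(d)
        if spec.merge == "outer_product" and spec.source_width(d) > self.outer_cap:
            raise ValueError(
                f"outer-product head at width {d} exceeds outer_cap={self.outer_cap}")
        rng = np.random.default_rng(self.seed)
        h = spec.hidden_width
        params: dict[str, np.ndarray] = {
            "W1": rng.standard_normal((h, f)) / np.sqrt(f),
            "b1": np.zeros(h),
            "w2": rng.standard_normal(h) / np.sqrt(h),
            "b2": np.zeros(1),
        }
        if spec.merge == "linear":
            sw = spec.source_width(d)
            if self.antisymmetric:
                params["w_tied"] = np.ones(sw)
            else:
                params["w_wt"] = np.ones(sw)
                params["w_mt"] = np.ones(sw)
        self.params_ = params
        self.loss_trace_ = np.empty(0)
        return self

    # forward / backward -------------------------------------------------

    def _sources(self, pair: VariantPair) -> tuple[np.ndarray, np.ndarray, dict]:
        """Raw per-sequence vectors plus cached tensors for backprop.

        When the backbone is a trainable mock and not frozen, the projection
        is applied here so its gradient can be taken; otherwise embeddings
        are constants.
        """
        bb = self.backbone_
        through_proj = (isinstance(bb, MockBackbone) and bb.trainable
                        and not self.freeze_backbone)
        if through_proj:
            raw_wt = bb.raw_embed(pair.wt_seq)
            raw_mt = bb.raw_embed(pair.mt_seq)
            emb_wt = EmbeddingMatrix(raw_wt @ bb.proj.T + bb.bias)
            emb_mt = EmbeddingMatrix(raw_mt @ bb.proj.T + bb.bias)
        else:
            raw_wt = raw_mt = None
            emb_wt = bb.embed(pair.wt_seq)
            emb_mt = bb.embed(pair.mt_seq)
        e_wt = select_rows(self.spec, emb_wt, pair.position)
        e_mt = select_rows(self.spec, emb_mt, pair.position)
        cache = {"raw_wt": raw_wt, "raw_mt": raw_mt, "through_proj": through_proj,
                 "position": pair.position}
        return e_wt, e_mt, cache

    def _merge_forward(self, e_wt: np.ndarray, e_mt: np.ndarray) -> np.ndarray:
        p = self.params_
        if self.merge == "concatenation":
            return np.concatenate([e_wt, e_mt])
        if self.merge == "outer_product":
            return np.outer(e_wt, e_mt).ravel()
        if self.antisymmetric:
            return p["w_tied"] * (e_wt - e_mt)
        return p["w_wt"] * e_wt + p["w_mt"] * e_mt

    def _forward(self, pair: VariantPair) -> tuple[float, dict]:
        e_wt, e_mt, cache = self._sources(pair)
        feat = self._merge_forward(e_wt, e_mt)
        p = self.params_
        pre = p["W1"] @ feat + p["b1"]
        hid = np.tanh(pre)
        y = float(p["w2"] @ hid + p["b2"][0])
        cache.update(e_wt=e_wt, e_mt=e_mt, feat=feat, hid=hid)
        return y, cache

    def _backward(self, dy: float, cache: dict) -> dict[str, np.ndarray]:
        """Gradients of dy * y with respect to every trainable array."""
        p = self.params_
        feat, hid = cache["feat"], cache["hid"]
        e_wt, e_mt = cache["e_wt"], cache["e_mt"]
        grads: dict[str, np.ndarray] = {}
        dhid = dy * p["w2"]
        grads["w2"] = dy * hid
        grads["b2"] = np.array([dy])
        dpre = dhid * (1.0 - hid ** 2)
        grads["W1"] = np.outer(dpre, feat)
        grads["b1"] = dpre
        dfeat = p["W1"].T @ dpre

        if self.merge == "concatenation":
            d = e_wt.size
            de_wt, de_mt = dfeat[:d], dfeat[d:]
        elif self.merge == "outer_product":
            m = dfeat.reshape(e_wt.size, e_mt.size)
            de_wt = m @ e_mt
            de_mt = m.T @ e_wt
        elif self.antisymmetric:
            grads["w_tied"] = dfeat * (e_wt - e_mt)
            de_wt = dfeat * p["w_tied"]
            de_mt = -de_wt
        else:
            grads["w_wt"] = dfeat * e_wt
            grads["w_mt"] = dfeat * e_mt
            de_wt = dfeat * p["w_wt"]
            de_mt = dfeat * p["w_mt"]

        if cache["through_proj"]:
            bb = self.backbone_
            pos = cache["position"]
            grads["bb.proj"] = np.zeros_like(bb.proj)
            grads["bb.bias"] = np.zeros_like(bb.bias)
            for de, raw in ((de_wt, cache["raw_wt"]), (de_mt, cache["raw_mt"])):
                rows, des = [], []
                if self.embedding_source == "position":
                    rows, des = [raw[pos + 1]], [de]
                elif self.embedding_source == "cls":
                    rows, des = [raw[0]], [de]
                else:
                    dd = de.size // 2
                    rows, des = [raw[0], raw[pos + 1]], [de[:dd], de[dd:]]
                for r, g in zip(rows, des):
                    grads["bb.proj"] += np.outer(g, r)
                    grads["bb.bias"] += g
        return grads

    # sklearn surface ----------------------------------------------------

    def fit(self, X, y=None) -> "HeadRegressor":
        """Train on a sequence of :class:`VariantPair`.

        ``y`` defaults to the pairs' own ``ddg`` targets.  Training follows
        the fine-tuning recipe (Adam, batch size one, linear warmup/decay);
        see :mod:`ddgpred.training`.
        """
        from .training import TrainConfig, train_initialized

        pairs = list(X)
        if y is None:
            y = [p.ddg for p in pairs]
        y = np.asarray(y, dtype=float)
        if len(pairs) == 0:
            raise ValueError("empty training set")
        if len(y) != len(pairs) or not np.isfinite(y).all():
            raise ValueError("targets must be finite and match the pairs")
        self.initialize()
        config = TrainConfig(
            peak_lr=self.learning_rate, warmup_fraction=self.warmup_fraction,
            epochs=self.epochs, batch_size=self.batch_size, seed=self.seed,
            freeze_backbone=self.freeze_backbone)
        train_initialized(self, pairs, y, config)
        return self

    def predict(self, X) -> np.ndarray:
        self._check_initialized()
        single = isinstance(X, VariantPair)
        pairs = [X] if single else list(X)
        out = np.array([self._forward(p)[0] for p in pairs])
        if not np.isfinite(out).all():
            raise FloatingPointError("non-finite prediction")
        return out

    def predict_one(self, pair: VariantPair) -> float:
        return float(self.predict([pair])[0])

    def trainable_arrays(self) -> dict[str, np.ndarray]:
        """All arrays updated by the optimizer, backbone included unless
        frozen; ``bb.`` prefixes name backbone parameters."""
        self._check_initialized()
        arrays = dict(self.params_)
        if self.antisymmetric:
            # biases stay frozen at zero to keep the head an odd function
            arrays.pop("b1")
            arrays.pop("b2")
        if not self.freeze_backbone and hasattr(self.backbone_, "parameters"):
            for k, v in self.backbone_.parameters().items():
                arrays[f"bb.{k}"] = v
        return arrays


class EnsembleRegressor(BaseEstimator, RegressorMixin):
    """Ensemble of the five admissible heads; the prediction is their
    arithmetic mean.

    Each member trains as an independent run with a seed derived from
    ``seed`` and its index, all over backbones of the same configuration.
    """

    def __init__(self, hidden_width: int = 128, antisymmetric: bool = False,
                 backbone_factory=None, learning_rate: float = 1e-5,
                 warmup_fraction: float = 0.30, epochs: int = 3,
                 seed: int = 0, freeze_backbone: bool = False,
                 outer_cap: int = 256):
        self.hidden_width = hidden_width
        self.antisymmetric = antisymmetric
        self.backbone_factory = backbone_factory
        self.learning_rate = learning_rate
        self.warmup_fraction = warmup_fraction
        self.epochs = epochs
        self.seed = seed
        self.freeze_backbone = freeze_backbone
        self.outer_cap = outer_cap

    def _make_members(self) -> dict[str, HeadRegressor]:
        members = {}
        for i, (source, merge) in enumerate(ADMISSIBLE_HEADS):
            backbone = (self.backbone_factory() if self.backbone_factory
                        else MockBackbone(seed=self.seed))
            members[f"{source}-{merge}"] = HeadRegressor(
                embedding_source=source, merge=merge,
                hidden_width=self.hidden_width,
                antisymmetric=self.antisymmetric and merge == "linear",
                backbone=backbone, learning_rate=self.learning_rate,
                warmup_fraction=self.warmup_fraction, epochs=self.epochs,
                seed=self.seed + 1 + i, freeze_backbone=self.freeze_backbone,
                outer_cap=self.outer_cap)
        return members

    def fit(self, X, y=None) -> "EnsembleRegressor":
        self.members_ = self._make_members()
        for member in self.members_.values():
            member.fit(X, y)
        return self

    def initialize(self) -> "EnsembleRegressor":
        self.members_ = self._make_members()
        for member in self.members_.values():
            member.initialize()
        return self

    def _check_members(self) -> None:
        if not hasattr(self, "members_"):
            raise NotFittedError("ensemble is not fitted")
        missing = [name for name, _ in
                   ((f"{s}-{m}", None) for s, m in ADMISSIBLE_HEADS)
                   if name not in self.members_]
        if missing:
            raise ValueError(f"ensemble is missing head(s): {missing}")

    def predict(self, X) -> np.ndarray:
        self._check_members()
        preds = [self.members_[f"{s}-{m}"].predict(X) for s, m in ADMISSIBLE_HEADS]
        return np.mean(preds, axis=0)


def predict(model, pair: VariantPair) -> float:
    """ddG estimate for one variant pair from any fitted head/ensemble."""
    return float(np.asarray(model.predict([pair]))[0])


def predict_ensemble(ensemble: EnsembleRegressor, pair: VariantPair) -> float:
    ensemble._check_members()
    return predict(ensemble, pair)
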