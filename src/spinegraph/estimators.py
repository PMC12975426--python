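"""Scikit-learn style estimators wrapping the segmentation networks.

These are the primary user-facing API: ``fit`` trains on lists of
(volume, label-map) arrays, ``predict`` returns label maps, and
``get_params``/``set_params`` make the estimators compose with sklearn
model selection.  Fitted state carries a trailing underscore
(``net_``, ``history_``, ``classes_``).

The estimators consume arrays already on a uniform grid (see
:mod:`spinegraph.pipeline` for preprocessing raw volumes); grids must be
divisible by ``2**(encoder_stages - 1)``.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .anatomy import DEFAULT_LEVELS, full_graph
from .networks import (Checkpoint, CoarseNetConfig, RefineNetConfig, TrainConfig,
                       build_coarse_net, build_refine_net, train_model)
from .pipeline import IdentityRefiner, run_two_stage
from .preprocess import PreprocessConfig, resize_probmap
from .volumes import as_array

__all__ = ["CoarseSpineSegmenter", "SliceRefineSegmenter", "TwoStageSpineParser"]


def _check_samples(X, y):
    if len(X) == 0 or len(X) != len(y):
        raise ValueError(f"need equally many volumes and label maps, "
                         f"got {len(X)} and {len(y)}")
    pairs = []
    for vol, lab in zip(X, y):
        v = as_array(vol).astype(np.float32)
        l = as_array(lab)
        if v.shape != l.shape:
            raise ValueError(f"volume {v.shape} and labels {l.shape} differ")
        pairs.append((v, l))
    return pairs


class CoarseSpineSegmenter(BaseEstimator):
    """3D graph-convolutional coarse segmentation (GCSN) estimator.

    Parameters mirror the network and training configuration; with
    ``use_semantic_block=False`` the estimator is the plain residual U-Net
    ablation, identical in every other parameter.
    """

    def __init__(self, levels=DEFAULT_LEVELS, encoder_stages=4, base_channels=32,
                 gcn_layers=2, deep_supervision_levels=2, use_semantic_block=True,
                 iterations=300, learning_rate=3e-3, dice_weight=1.0,
                 ce_weight=1.0, aux_weights=(0.5, 0.25), assign_weight=1.0,
                 augment=False, random_state=0):
        self.levels = levels
        self.encoder_stages = encoder_stages
        self.base_channels = base_channels
        self.gcn_layers = gcn_layers
        self.deep_supervision_levels = deep_supervision_levels
        self.use_semantic_block = use_semantic_block
        self.iterations = iterations
        self.learning_rate = learning_rate
        self.dice_weight = dice_weight
        self.ce_weight = ce_weight
        self.aux_weights = aux_weights
        self.assign_weight = assign_weight
        self.augment = augment
        self.random_state = random_state

    def _configs(self):
        graph = full_graph(self.levels)
        net_cfg = CoarseNetConfig(
            encoder_stages=self.encoder_stages, base_channels=self.base_channels,
            classes=graph.n_nodes + 1, gcn_layers=self.gcn_layers,
            deep_supervision_levels=self.deep_supervision_levels,
            use_semantic_block=self.use_semantic_block)
        train_cfg = TrainConfig(
            seed=self.random_state, iterations=self.iterations,
            learning_rate=self.learning_rate, dice_weight=self.dice_weight,
            ce_weight=self.ce_weight, aux_weights=tuple(self.aux_weights),
            assign_weight=self.assign_weight, augment=self.augment)
        return graph, net_cfg, train_cfg

    def fit(self, X, y):
        """Train on sequences of volumes and integer label maps."""
        pairs = _check_samples(X, y)
        graph, net_cfg, train_cfg = self._configs()
        self.graph_ = graph
        self.classes_ = np.arange(net_cfg.classes)
        self.net_ = build_coarse_net(net_cfg, graph=graph, seed=self.random_state)
        self.checkpoint_ = train_model(self.net_, pairs, train_cfg)
        self.history_ = list(self.checkpoint_.history)
        return self

    def predict_proba(self, X):
        """Per-voxel class probabilities, one (C+1, D, H, W) array per volume."""
        self._check_fitted()
        return [self.net_.predict_proba(as_array(v)) for v in X]

    def predict(self, X):
        """Argmax label maps (ties -> lowest class index)."""
        return [np.argmax(p, axis=0).astype(np.int16) for p in self.predict_proba(X)]

    def score(self, X, y):
        """Mean foreground Dice over present structures, averaged over subjects."""
        from .metrics import dice_coefficient
        self._check_fitted()
        scores = []
        for pred, gt in zip(self.predict(X), y):
            gt = as_array(gt)
            per = [dice_coefficient(pred, gt, lab.id) for lab in self.graph_.labels]
            per = [d for d in per if not np.isnan(d)]
            scores.append(np.mean(per))
        return float(np.mean(scores))

    def _check_fitted(self):
        if not hasattr(self, "net_"):
            raise RuntimeError("estimator is not fitted; call fit first")


class SliceRefineSegmenter(BaseEstimator):
    """2D residual refinement estimator over fused image+probability slices.

    ``fit`` takes per-subject high-resolution volumes, coarse probability
    volumes (C+1, D, H, W) aligned to them, and label maps; it trains on the
    pooled slice set.
    """

    def __init__(self, levels=DEFAULT_LEVELS, encoder_stages=5, base_channels=32,
                 iterations=200, learning_rate=3e-3, dice_weight=1.0,
                 ce_weight=1.0, random_state=0):
        self.levels = levels
        self.encoder_stages = encoder_stages
        self.base_channels = base_channels
        self.iterations = iterations
        self.learning_rate = learning_rate
        self.dice_weight = dice_weight
        self.ce_weight = ce_weight
        self.random_state = random_state

    def fit(self, X, coarse_probs, y):
        n_classes = len(full_graph(self.levels).labels) + 1
        slices = []
        for vol, probs, lab in zip(X, coarse_probs, y):
            vol = as_array(vol)
            lab = as_array(lab)
            probs = np.asarray(probs)
            if probs.shape[0] != n_classes:
                raise ValueError(f"expected {n_classes} probability channels, "
                                 f"got {probs.shape[0]}")
            if probs.shape[1:] != vol.shape:
                probs = resize_probmap(probs, vol.shape)
            for i in range(vol.shape[0]):
                fused = np.concatenate([vol[i][None], probs[:, i]])
                slices.append((fused.astype(np.float32), lab[i]))
        cfg = RefineNetConfig(encoder_stages=self.encoder_stages,
                              base_channels=self.base_channels,
                              in_channels=1 + n_classes, classes=n_classes)
        self.net_ = build_refine_net(cfg, seed=self.random_state)
        train_cfg = TrainConfig(seed=self.random_state, iterations=self.iterations,
                                learning_rate=self.learning_rate,
                                dice_weight=self.dice_weight,
                                ce_weight=self.ce_weight, aux_weights=())
        self.checkpoint_ = train_model(self.net_, slices, train_cfg)
        self.history_ = list(self.checkpoint_.history)
        return self

    def refine_slices(self, image_slices, prob_slices):
        if not hasattr(self, "net_"):
            raise RuntimeError("estimator is not fitted; call fit first")
        return self.net_.refine_slices(image_slices, prob_slices)


class TwoStageSpineParser(BaseEstimator):
    """Coarse 3D parsing + 2D slice refinement as one estimator.

    ``refiner="identity"`` skips learned refinement and reproduces the
    upsampled coarse argmax (useful as a consistency baseline and for
    ablation studies).
    """

    def __init__(self, coarse=None, refiner="identity",
                 preprocess=None, random_state=0):
        self.coarse = coarse
        self.refiner = refiner
        self.preprocess = preprocess
        self.random_state = random_state

    def _preprocess_config(self):
        return self.preprocess or PreprocessConfig.phantom_scale()

    def fit(self, X, y):
        from .pipeline import preprocess_pair
        cfg = self._preprocess_config()
        self.coarse_ = self.coarse or CoarseSpineSegmenter(
            random_state=self.random_state)
        coarse_pairs = [preprocess_pair(v, l, cfg, to_coarse=True)
                        for v, l in zip(X, y)]
        self.coarse_.fit([p[0] for p in coarse_pairs],
                         [p[1] for p in coarse_pairs])
        if self.refiner == "identity":
            self.refiner_ = IdentityRefiner()
        else:
            highres = [preprocess_pair(v, l, cfg, to_coarse=False)
                       for v, l in zip(X, y)]
            probs = [self.coarse_.net_.predict_proba(p[0])
                     for p in (preprocess_pair(v, l, cfg, to_coarse=True)
                               for v, l in zip(X, y))]
            self.refiner_ = self.refiner
            self.refiner_.fit([h[0] for h in highres], probs,
                              [h[1] for h in highres])
        return self

    def predict(self, X):
        if not hasattr(self, "coarse_"):
            raise RuntimeError("estimator is not fitted; call fit first")
        cfg = self._preprocess_config()
        return [run_two_stage(v, self.coarse_.net_, self.refiner_, cfg)
                for v in X]
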