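"""Trainable segmentation operators.

* :class:`CoarseNet` -- the 3D graph-convolutional segmentation network
  (GCSN): a residual encoder--decoder whose bottleneck converts voxel
  features into per-structure node features, propagates them along the
  anatomical adjacency and projects them back (the semantic block).  With
  ``use_semantic_block=False`` the very same network is the ResUNet
  ablation: the two differ only in the semantic-block parameters.
* :class:`RefineNet` -- the 2D residual refinement network consuming a
  high-resolution image slice fused with the coarse probability slices.
* Dice + cross-entropy deep-supervision loss and a seeded single-sample
  training loop producing reloadable checkpoints.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .anatomy import AnatomyGraph, full_graph
from .nn import autodiff as ad
from .nn.autodiff import Tensor
from .nn.layers import Conv, ConvBlock, Down, Module, ResBlock, Up
from .nn.losses import dice_ce_value, one_hot, soft_dice_ce
from .nn.optim import Adam
from .preprocess import PreprocessConfig, augment_sample
from .semantic import SemanticParams, semantic_block
from .volumes import as_array

__all__ = [
    "CoarseNetConfig",
    "RefineNetConfig",
    "TrainConfig",
    "CoarseNet",
    "RefineNet",
    "Checkpoint",
    "build_coarse_net",
    "build_refine_net",
    "segmentation_loss",
    "train_model",
]


@dataclass
class CoarseNetConfig:
    encoder_stages: int = 4
    base_channels: int = 32
    classes: int = 20  # C foreground structures + background
    gcn_layers: int = 2
    deep_supervision_levels: int = 2
    use_semantic_block: bool = True
    mass_floor: float = 1.0  # voxels of probability mass; stabilizes pooling

    def __post_init__(self):
        if self.encoder_stages < 2:
            raise ValueError("encoder_stages must be >= 2")
        if self.base_channels < 1:
            raise ValueError("base_channels must be >= 1")


@dataclass
class RefineNetConfig:
    encoder_stages: int = 5
    base_channels: int = 32
    in_channels: int = 21  # image + C+1 probability channels
    classes: int = 20


@dataclass
class TrainConfig:
    seed: int = 0
    iterations: int = 300
    batch_size: int = 1
    learning_rate: float = 3e-3
    dice_weight: float = 1.0
    ce_weight: float = 1.0
    aux_weights: tuple = (0.5, 0.25)
    assign_weight: float = 1.0
    augment: bool = False
    use_gt_assignment: bool = False  # pool over ground-truth masks (ablation)

    def __post_init__(self):
        ws = (self.dice_weight, self.ce_weight)
        if any(w < 0 for w in ws) or not any(w > 0 for w in ws):
            raise ValueError("loss weights must be >= 0 with at least one > 0")


def _check_divisible(spatial, stages):
    f = 2 ** (stages - 1)
    bad = [s for s in spatial if s % f != 0]
    if bad:
        need = tuple(int(np.ceil(s / f) * f) for s in spatial)
        raise ValueError(
            f"input spatial dims {tuple(spatial)} must be divisible by {f} "
            f"for a {stages}-stage encoder; pad to {need}")


class _EncoderDecoder(Module):
    """Shared residual encoder--decoder backbone (2D or 3D)."""

    def __init__(self, nd, in_channels, cfg_stages, base, classes, rng):
        self.nd = nd
        self.stages = cfg_stages
        self.classes = classes
        chans = [base * 2 ** i for i in range(cfg_stages)]
        self.chans = chans
        self.stem = ConvBlock(nd, in_channels, chans[0], rng=rng)
        self.enc = [ResBlock(nd, c, rng=rng) for c in chans]
        self.down = [Down(nd, chans[i], chans[i + 1], rng=rng)
                     for i in range(cfg_stages - 1)]
        self.up = [Up(nd, chans[i + 1], chans[i], rng=rng)
                   for i in range(cfg_stages - 1)]
        self.head = Conv(nd, chans[0], classes, k=1, rng=rng)

    def encode(self, x: Tensor):
        h = self.stem(x)
        skips = []
        for i in range(self.stages):
            h = self.enc[i](h)
            if i < self.stages - 1:
                skips.append(h)
                h = self.down[i](h)
        return h, skips

    def decode(self, h: Tensor, skips):
        feats = []
        for i in range(self.stages - 2, -1, -1):
            h = self.up[i](h, skips[i])
            feats.append((i, h))
        return h, feats


class CoarseNet(Module):
    """3D GCSN; set ``use_semantic_block=False`` for the ResUNet ablation."""

    def __init__(self, config: CoarseNetConfig, graph: AnatomyGraph | None = None,
                 seed: int = 0):
        self.config = config
        self.graph = graph or full_graph()
        if self.graph.n_nodes != config.classes - 1:
            raise ValueError(
                f"graph has {self.graph.n_nodes} nodes but config expects "
                f"{config.classes - 1} foreground classes")
        rng = np.random.default_rng(seed)
        self.backbone = _EncoderDecoder(3, 1, config.encoder_stages,
                                        config.base_channels, config.classes, rng)
        deep_c = self.backbone.chans[-1]
        if config.use_semantic_block:
            self.assign_head = Conv(3, deep_c, config.classes, k=1, rng=rng)
            scale = 1.0 / np.sqrt(deep_c)
            self.gcn_weights = [
                Tensor(rng.normal(0.0, scale, (deep_c, deep_c)).astype(np.float32),
                       requires_grad=True)
                for _ in range(config.gcn_layers)]
            self.proj_w = Tensor(np.zeros((deep_c, deep_c), dtype=np.float32),
                                 requires_grad=True)
            self.proj_b = Tensor(np.zeros(deep_c, dtype=np.float32),
                                 requires_grad=True)
        # aux heads on the coarsest decoder outputs
        n_aux = min(config.deep_supervision_levels, config.encoder_stages - 2)
        self.aux_heads = [Conv(3, self.backbone.chans[config.encoder_stages - 2 - j],
                               config.classes, k=1, rng=rng)
                          for j in range(n_aux)]

    def forward(self, x: Tensor, gt_assign: np.ndarray | None = None):
        """Return (main_logits, [(aux_logits, factor), ...], assign_probs).

        ``assign_probs`` is the (1, C+1, d, h, w) bottleneck soft assignment
        (None for the ablation); aux ``factor`` is the downsampling factor
        of that output relative to the input grid.  ``gt_assign`` optionally
        supplies ground-truth foreground masks (C, d, h, w) on the
        bottleneck grid to drive region pooling (ablation mode); the
        assignment head is still computed and supervised.
        """
        _check_divisible(x.data.shape[2:], self.config.encoder_stages)
        h, skips = self.backbone.encode(x)
        assign_probs = None
        aux = []
        if self.config.use_semantic_block:
            assign_logits = self.assign_head(h)
            assign_probs = ad.softmax_channels(assign_logits)
            fg = ad.narrow(assign_probs, 1, 1, self.config.classes - 1)
            spatial = h.data.shape[2:]
            f2 = ad.reshape(h, (h.data.shape[1], -1))
            if gt_assign is not None:
                if gt_assign.shape != (self.config.classes - 1,) + spatial:
                    raise ValueError(
                        f"gt_assign shape {gt_assign.shape} does not match "
                        f"(C, {spatial})")
                p2 = Tensor(gt_assign.reshape(self.config.classes - 1, -1)
                            .astype(np.float32))
            else:
                p2 = ad.reshape(fg, (self.config.classes - 1, -1))
            params = SemanticParams(gcn_weights=self.gcn_weights,
                                    proj_w=self.proj_w, proj_b=self.proj_b)
            h = ad.reshape(
                semantic_block(f2, p2, self.graph, params,
                               mass_floor=self.config.mass_floor),
                (1, h.data.shape[1]) + spatial)
            aux.append((assign_logits, 2 ** (self.config.encoder_stages - 1)))
        h, feats = self.backbone.decode(h, skips)
        for j, head in enumerate(self.aux_heads):
            level, feat = feats[j]
            aux.append((head(feat), 2 ** level))
        main = self.backbone.head(h)
        return main, aux, assign_probs

    def predict_proba(self, volume: np.ndarray) -> np.ndarray:
        """Per-voxel class probabilities (C+1, D, H, W) for one volume."""
        x = Tensor(np.asarray(volume, dtype=np.float32)[None, None])
        main, _, _ = self.forward(x)
        z = main.data[0] - main.data[0].max(axis=0, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=0, keepdims=True)


class RefineNet(Module):
    """2D residual refinement network over fused image+probability slices."""

    def __init__(self, config: RefineNetConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        self.backbone = _EncoderDecoder(2, config.in_channels, config.encoder_stages,
                                        config.base_channels, config.classes, rng)

    def forward(self, x: Tensor):
        if x.data.shape[1] != self.config.in_channels:
            raise ValueError(
                f"fused slice stack has {x.data.shape[1]} channels, expected "
                f"{self.config.in_channels}")
        _check_divisible(x.data.shape[2:], self.config.encoder_stages)
        h, skips = self.backbone.encode(x)
        h, _ = self.backbone.decode(h, skips)
        return self.backbone.head(h), [], None

    def predict_proba(self, fused_slice: np.ndarray) -> np.ndarray:
        x = Tensor(np.asarray(fused_slice, dtype=np.float32)[None])
        main, _, _ = self.forward(x)
        z = main.data[0] - main.data[0].max(axis=0, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=0, keepdims=True)

    def refine_slices(self, image_slices, prob_slices):
        """Refine every (image, coarse-prob) slice pair; returns prob slices."""
        out = []
        for img, probs in zip(image_slices, prob_slices):
            fused = np.concatenate([np.asarray(img)[None], np.asarray(probs)])
            out.append(self.predict_proba(fused))
        return out


def build_coarse_net(config: CoarseNetConfig | None = None,
                     graph: AnatomyGraph | None = None, seed: int = 0) -> CoarseNet:
    return CoarseNet(config or CoarseNetConfig(), graph=graph, seed=seed)


def build_refine_net(config: RefineNetConfig | None = None, seed: int = 0) -> RefineNet:
    return RefineNet(config or RefineNetConfig(), seed=seed)


# ---------------------------------------------------------------------------
# loss and training
# ---------------------------------------------------------------------------

def _downsample_labels(target: np.ndarray, factor: int) -> np.ndarray:
    if factor == 1:
        return target
    sl = tuple(slice(None, None, factor) for _ in range(target.ndim))
    return target[sl]


def _soft_downsample(onehot: np.ndarray, factor: int) -> np.ndarray:
    """Block-averaged class fractions: (1, C, *S) -> (1, C, *S/factor).

    Deep-supervision targets at large factors keep the probability mass of
    thin structures (a nearest-subsampled grid drops them entirely).
    """
    if factor == 1:
        return onehot
    n, c = onehot.shape[:2]
    spatial = onehot.shape[2:]
    if any(s % factor for s in spatial):
        raise ValueError(f"spatial dims {spatial} not divisible by {factor}")
    shape = (n, c) + tuple(x for s in spatial for x in (s // factor, factor))
    axes = tuple(3 + 2 * i for i in range(len(spatial)))
    return onehot.reshape(shape).mean(axis=axes)


def segmentation_loss(main_probs, aux_probs, target, dice_w: float = 1.0,
                      ce_w: float = 1.0, aux_weights=(0.5, 0.25)) -> float:
    """Dice+CE over the main output plus weighted auxiliary outputs.

    Evaluation-path variant over probability maps; auxiliary targets are the
    nearest-downsampled label grids matching each auxiliary resolution.
    """
    target = as_array(target)
    loss = dice_ce_value(main_probs, target, dice_w, ce_w)
    for w, probs in zip(aux_weights, aux_probs):
        probs = np.asarray(probs)
        factor = target.shape[-1] // probs.shape[-1]
        loss += w * dice_ce_value(probs, _downsample_labels(target, factor),
                                  dice_w, ce_w)
    return loss


def _training_loss(net, x: Tensor, target: np.ndarray, cfg: TrainConfig) -> Tensor:
    semantic = getattr(net.config, "use_semantic_block", False)
    if cfg.use_gt_assignment and semantic:
        factor = 2 ** (net.config.encoder_stages - 1)
        oh = one_hot(target, net.config.classes)
        gt_assign = _soft_downsample(oh, factor)[0, 1:]
        main, aux, _ = net.forward(x, gt_assign=gt_assign)
    else:
        main, aux, _ = net.forward(x)
    loss = soft_dice_ce(main, target, cfg.dice_weight, cfg.ce_weight)
    oh_full = one_hot(target, net.config.classes) if aux else None
    k = 0
    for logits, factor in aux:
        if factor == 2 ** (net.config.encoder_stages - 1) and \
                getattr(net.config, "use_semantic_block", False):
            w = cfg.assign_weight
        else:
            w = cfg.aux_weights[k % len(cfg.aux_weights)] if cfg.aux_weights else 0.0
            k += 1
        if w == 0.0:
            continue
        t = _soft_downsample(oh_full, factor)
        term = soft_dice_ce(logits, t, cfg.dice_weight, cfg.ce_weight)
        loss = _weighted_add(loss, term, w)
    return loss


def _weighted_add(a: Tensor, b: Tensor, w: float) -> Tensor:
    """a + w*b with the weight folded into the backward seed of b."""
    out = Tensor(a.data + w * b.data)
    out.requires_grad = a.requires_grad or b.requires_grad
    if out.requires_grad:
        out._parents = tuple(t for t in (a, b) if t.requires_grad)

        def backward(g):
            if a.requires_grad:
                a.accumulate(g)
            if b.requires_grad:
                b.accumulate(g * w)

        out._backward = backward
    return out


@dataclass
class Checkpoint:
    """Reloadable parameter blob + config snapshot + training history."""

    kind: str  # "coarse" | "refine"
    config: dict
    state: dict
    history: list = field(default_factory=list)

    def save(self, path) -> None:
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.state)
        sidecar = {"kind": self.kind, "config": self.config,
                   "history": list(map(float, self.history))}
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path) -> "Checkpoint":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        with np.load(path.with_suffix(".npz")) as blob:
            state = {k: blob[k] for k in blob.files}
        return cls(kind=sidecar["kind"], config=sidecar["config"], state=state,
                   history=sidecar["history"])

    def build_net(self, graph: AnatomyGraph | None = None):
        if self.kind == "coarse":
            net = CoarseNet(CoarseNetConfig(**_tupleize(self.config)), graph=graph)
        elif self.kind == "refine":
            net = RefineNet(RefineNetConfig(**_tupleize(self.config)))
        else:
            raise ValueError(f"unknown checkpoint kind {self.kind!r}")
        net.load_state_dict(self.state)
        return net


def _tupleize(cfg: dict) -> dict:
    return {k: tuple(v) if isinstance(v, list) else v for k, v in cfg.items()}


def train_model(net, samples, config: TrainConfig,
                progress: bool = False) -> Checkpoint:
    """Seeded stochastic training over (volume, labelmap) sample pairs.

    ``samples`` is a sequence of (image array, integer label array) on the
    network's input grid.  One sample is drawn per iteration (batch 1 for
    the 3D net).  Training aborts on a non-finite loss.  Deterministic for a
    fixed seed and sample list.
    """
    samples = list(samples)
    if not samples:
        raise ValueError("no training samples")
    rng = np.random.default_rng(config.seed)
    opt = Adam(net.params(), lr=config.learning_rate)
    history = []
    aug_cfg = PreprocessConfig.phantom_scale() if config.augment else None
    is_refine = isinstance(net, RefineNet)
    for it in range(config.iterations):
        vol, lab = samples[int(rng.integers(len(samples)))]
        if config.augment and not is_refine:
            vol, lab = augment_sample(vol, lab, rng, aug_cfg)
            vol = as_array(vol)
            lab = as_array(lab)
        arr = np.asarray(vol, dtype=np.float32)
        # refine samples are fused (channels, H, W) stacks; coarse are volumes
        x = Tensor(arr[None] if is_refine else arr[None, None])
        loss = _training_loss(net, x, np.asarray(lab), config)
        if not np.isfinite(loss.data):
            raise RuntimeError(
                f"non-finite loss {loss.data!r} at iteration {it}; aborting")
        net.zero_grad()
        loss.backward()
        opt.step()
        history.append(float(loss.data))
        if progress and (it + 1) % 25 == 0:
            print(f"  iter {it + 1}/{config.iterations}  loss {loss.data:.4f}")
    kind = "coarse" if isinstance(net, CoarseNet) else "refine"
    return Checkpoint(kind=kind, config=asdict(net.config),
                      state=net.state_dict(), history=history)
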