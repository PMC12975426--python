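"""Graph-based semantic feature extraction.

This is the heart of the coarse segmentation network: dense voxel features
are condensed into one feature vector per anatomical structure (region
pooling), information is propagated along the vertebra--disc chain by graph
convolution, and the updated node features are redistributed onto the voxel
grid (region unpooling) and fused back into the CNN stream through a
residual projection.

All three operators accept either plain NumPy arrays (pure functions, used
directly in tests and analyses) or :class:`~spinegraph.nn.autodiff.Tensor`
nodes (differentiable, used inside the networks).  Shapes:

* features ``f``: ``(F, D, H, W)`` or ``(F, V)``
* soft assignment ``p``: ``(C, D, H, W)`` or ``(C, V)`` -- one channel per
  foreground structure, entries in [0, 1], per-voxel sum <= 1
* node features ``H``: ``(C, F)``, row k belonging to structure id k

Region pooling computes the probability-weighted mean
``h_k = sum_v p_kv f_v / sum_v p_kv`` (zero row when a structure has no
mass -- phantom subjects may lack the cranial levels).  Unpooling
renormalizes the foreground probabilities per voxel and sums
``f'_v = sum_k p_kv / (sum_j p_jv) h_k``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .anatomy import AnatomyGraph
from .nn.autodiff import Tensor, matmul, relu

__all__ = [
    "MASS_EPS",
    "region_pool",
    "graph_convolve",
    "region_unpool",
    "SemanticParams",
    "semantic_block",
]

#: Pooled-mass threshold below which a structure is treated as absent.
MASS_EPS = 1e-8


def _flat2(x, name):
    """View (X, D, H, W) as (X, V); returns (array, spatial_shape)."""
    arr = x.data if isinstance(x, Tensor) else np.asarray(x)
    if arr.ndim < 2:
        raise ValueError(f"{name} must be at least 2D, got shape {arr.shape}")
    return arr.reshape(arr.shape[0], -1), arr.shape[1:]


# ---------------------------------------------------------------------------
# region pooling
# ---------------------------------------------------------------------------

def _pool_kernel(f2: np.ndarray, p2: np.ndarray, mass_floor: float = 0.0):
    mass = p2.sum(axis=1)  # (C,)
    s = p2 @ f2.T  # (C, F)
    safe = mass >= MASS_EPS
    h = np.zeros_like(s)
    if mass_floor > 0.0:
        denom = np.maximum(mass, mass_floor)
        h[safe] = s[safe] / denom[safe, None]
        return h, denom, safe
    h[safe] = s[safe] / mass[safe, None]
    return h, np.where(safe, mass, 1.0), safe


def region_pool(features, assign, mass_floor: float = 0.0):
    """Probability-weighted mean feature per anatomical node.

    Returns ``H`` of shape (C, F); rows of structures with pooled mass below
    :data:`MASS_EPS` are zero.  A positive ``mass_floor`` clamps the
    denominator from below (in voxels of probability mass), bounding the
    gradient amplification for near-empty regions; the default 0 gives the
    exact probability-weighted mean.
    """
    f2, fsp = _flat2(features, "features")
    p2, psp = _flat2(assign, "assign")
    if fsp != psp:
        raise ValueError(f"spatial shapes differ: features {fsp} vs assignment {psp}")
    h, denom, safe = _pool_kernel(f2, p2, mass_floor)
    if not (isinstance(features, Tensor) or isinstance(assign, Tensor)):
        return h

    ft = features if isinstance(features, Tensor) else Tensor(features)
    pt = assign if isinstance(assign, Tensor) else Tensor(assign)
    out = Tensor(h)
    out.requires_grad = ft.requires_grad or pt.requires_grad
    if out.requires_grad:
        out._parents = tuple(t for t in (ft, pt) if t.requires_grad)
        mass = p2.sum(axis=1)
        # the denominator is locally constant where the clamp is active
        active = safe & (mass >= mass_floor) if mass_floor > 0.0 else safe

        def backward(g):
            gm = np.where(safe[:, None], g, 0.0)
            inv = np.where(safe, 1.0 / denom, 0.0)
            ds = gm * inv[:, None]  # (C, F)
            if ft.requires_grad:
                ft.accumulate((p2.T @ ds).T.reshape(ft.data.shape))
            if pt.requires_grad:
                dmass = np.where(active, -(gm * h).sum(axis=1) * inv, 0.0)  # (C,)
                dp = ds @ f2 + dmass[:, None]
                pt.accumulate(dp.reshape(pt.data.shape))

        out._backward = backward
    return out


# ---------------------------------------------------------------------------
# graph convolution
# ---------------------------------------------------------------------------

def graph_convolve(H, graph: AnatomyGraph, weight, activation: str = "relu"):
    """One propagation layer ``H' = act(A_hat H W)``.

    ``activation`` is ``"relu"`` or ``"linear"``.  Works on arrays or
    Tensors; ``weight`` may likewise be an array or a (trainable) Tensor.
    """
    if graph.A_hat is None:
        raise ValueError("graph.A_hat not set; call normalize_adjacency first")
    a_hat = np.asarray(graph.A_hat)
    h_arr = H.data if isinstance(H, Tensor) else np.asarray(H)
    w_arr = weight.data if isinstance(weight, Tensor) else np.asarray(weight)
    if np.ndim(w_arr) < 2:  # scalar / flat weights for the F=1 toy cases
        w_arr = np.asarray(w_arr, dtype=float).reshape(h_arr.shape[1], -1)
        if isinstance(weight, Tensor):
            raise ValueError("flat Tensor weights unsupported; pass a (F, F') matrix")
        weight = w_arr
    if h_arr.shape[0] != a_hat.shape[0]:
        raise ValueError(f"H has {h_arr.shape[0]} rows but graph has "
                         f"{a_hat.shape[0]} nodes")
    if h_arr.shape[1] != w_arr.shape[0]:
        raise ValueError(f"feature width {h_arr.shape[1]} does not match weight "
                         f"shape {w_arr.shape}")
    if activation not in ("relu", "linear"):
        raise ValueError(f"unknown activation {activation!r}")

    if not (isinstance(H, Tensor) or isinstance(weight, Tensor)):
        out = a_hat @ h_arr @ w_arr
        return np.maximum(out, 0.0) if activation == "relu" else out

    ht = H if isinstance(H, Tensor) else Tensor(h_arr)
    wt = weight if isinstance(weight, Tensor) else Tensor(w_arr)
    out = matmul(matmul(Tensor(a_hat), ht), wt)
    return relu(out) if activation == "relu" else out


# ---------------------------------------------------------------------------
# region unpooling
# ---------------------------------------------------------------------------

def _unpool_kernel(h: np.ndarray, p2: np.ndarray, mass_floor: float = 0.0):
    total = p2.sum(axis=0)  # (V,)
    safe = total >= MASS_EPS
    denom = np.maximum(total, mass_floor) if mass_floor > 0.0 else \
        np.where(safe, total, 1.0)
    pn = np.where(safe[None, :], p2 / denom[None, :], 0.0)
    out = h.T @ pn  # (F, V)
    return out, pn, total, denom, safe


def region_unpool(H, assign, mass_floor: float = 0.0):
    """Redistribute node features to voxels via renormalized probabilities.

    Returns a feature grid of shape (F, *spatial); voxels with total
    foreground mass below :data:`MASS_EPS` receive the zero vector.  A
    positive ``mass_floor`` clamps the per-voxel normalizer from below
    (numerical stabilization for the in-network block); the default 0 gives
    the exact renormalized weighting.
    """
    h_arr = H.data if isinstance(H, Tensor) else np.asarray(H)
    p2, psp = _flat2(assign, "assign")
    if h_arr.shape[0] != p2.shape[0]:
        raise ValueError(f"H has {h_arr.shape[0]} rows but assignment has "
                         f"{p2.shape[0]} channels")
    out2, pn, total, denom, safe = _unpool_kernel(h_arr, p2, mass_floor)
    out_shape = (h_arr.shape[1],) + tuple(psp)
    if not (isinstance(H, Tensor) or isinstance(assign, Tensor)):
        return out2.reshape(out_shape)

    ht = H if isinstance(H, Tensor) else Tensor(h_arr)
    pt = assign if isinstance(assign, Tensor) else Tensor(p2)
    out = Tensor(out2.reshape(out_shape))
    out.requires_grad = ht.requires_grad or pt.requires_grad
    if out.requires_grad:
        out._parents = tuple(t for t in (ht, pt) if t.requires_grad)
        # where the clamp is active the normalizer is locally constant
        active = safe & (total >= mass_floor) if mass_floor > 0.0 else safe

        def backward(g):
            g2 = g.reshape(g.shape[0], -1)  # (F, V)
            if ht.requires_grad:
                ht.accumulate(pn @ g2.T)  # (C, F)
            if pt.requires_grad:
                inv = np.where(safe, 1.0 / denom, 0.0)
                per_node = h_arr @ g2  # (C, V): sum_f g_fv h_kf
                common = np.where(active, (out2 * g2).sum(axis=0), 0.0)  # (V,)
                dp = (per_node - common[None, :]) * inv[None, :]
                pt.accumulate(dp.reshape(pt.data.shape))

        out._backward = backward
    return out


# ---------------------------------------------------------------------------
# full semantic block
# ---------------------------------------------------------------------------

@dataclass
class SemanticParams:
    """Weights of a semantic block: L graph layers plus a linear projection.

    ``gcn_weights[i]`` has shape (F, F); the final graph layer is linear,
    earlier ones pass through a rectifier.  The 1x1x1 projection (``proj_w``
    (F, F), ``proj_b`` (F,)) maps unpooled node features back into the CNN
    stream before the residual addition; zero-initialized projection makes
    the whole block the identity.
    """

    gcn_weights: list
    proj_w: np.ndarray
    proj_b: np.ndarray

    @classmethod
    def init(cls, n_features: int, n_layers: int = 2,
             rng: np.random.Generator | None = None) -> "SemanticParams":
        rng = rng or np.random.default_rng(0)
        scale = 1.0 / np.sqrt(n_features)
        ws = [rng.normal(0.0, scale, size=(n_features, n_features))
              for _ in range(n_layers)]
        return cls(gcn_weights=ws, proj_w=np.zeros((n_features, n_features)),
                   proj_b=np.zeros(n_features))


def semantic_block(features, assign, graph: AnatomyGraph, params: SemanticParams,
                   mass_floor: float = 0.0):
    """Pool -> L graph-convolution layers -> unpool -> project -> residual add.

    Accepts arrays (pure) or Tensors (differentiable).  The residual path
    guarantees the block degenerates to the identity when the projection is
    zero (and, with a linear final layer, when all graph weights are zero).
    ``mass_floor`` is forwarded to the pooling/unpooling normalizers.
    """
    tensor_mode = isinstance(features, Tensor) or isinstance(assign, Tensor)
    h = region_pool(features, assign, mass_floor=mass_floor)
    n_layers = len(params.gcn_weights)
    for i, w in enumerate(params.gcn_weights):
        act = "relu" if i < n_layers - 1 else "linear"
        h = graph_convolve(h, graph, w, activation=act)
    grid = region_unpool(h, assign, mass_floor=mass_floor)

    if not tensor_mode:
        f = np.asarray(features)
        g2 = grid.reshape(grid.shape[0], -1)
        proj = (np.asarray(params.proj_w) @ g2) + np.asarray(params.proj_b)[:, None]
        return f + proj.reshape(f.shape)

    from .nn.autodiff import add, reshape  # local import to keep module light
    ft = features if isinstance(features, Tensor) else Tensor(features)
    pw = params.proj_w if isinstance(params.proj_w, Tensor) else Tensor(params.proj_w)
    pb = params.proj_b if isinstance(params.proj_b, Tensor) else Tensor(params.proj_b)
    g2 = reshape(grid, (grid.data.shape[0], -1))
    proj = _add_colvec(matmul(pw, g2), pb)
    return add(ft, reshape(proj, ft.data.shape))


def _add_colvec(m: Tensor, v: Tensor) -> Tensor:
    """m (F, V) + v (F,) broadcast; differentiable."""
    out = Tensor(m.data + v.data[:, None])
    out.requires_grad = m.requires_grad or v.requires_grad
    if out.requires_grad:
        out._parents = tuple(t for t in (m, v) if t.requires_grad)

        def backward(g):
            if m.requires_grad:
                m.accumulate(g)
            if v.requires_grad:
                v.accumulate(g.sum(axis=1))

        out._backward = backward
    return out
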