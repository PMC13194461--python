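"""Hierarchical point-cloud semantic segmentation network.

The backbone is a PointNet++-style encoder/decoder: set-abstraction stages
(farthest-point sampling, radius grouping, shared MLP, max pooling) and
feature-propagation stages (k-NN inverse-distance interpolation plus skip
connections).  Four independently toggleable improvements target thin
stems and small cotyledons:

* multi-scale convolution blocks (parallel kernel 1/3/5 1D convolutions
  along the sampled point sequence, fused by a 1x1 convolution),
* squeeze-and-excitation channel attention inside each block,
* a global context module that broadcast-adds a bottlenecked scene
  descriptor to every point feature, and
* an improved feature-propagation layer that refines fused skip features
  with a multi-scale residual block before the final 1x1 mapping.

1D convolutions over an unordered point set need a canonical ordering; we
use the order produced by deterministic farthest-point sampling at each
level, which makes results reproducible (and documented as
order-dependent).  All math runs on :mod:`seedling3d.autograd` tensors.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial import cKDTree

from .autograd import Tensor, concat, conv1d, gather_points


# ----------------------------------------------------------------------
# configuration
# ----------------------------------------------------------------------

@dataclass
class StageConfig:
    """One set-abstraction stage."""

    n_points: int
    radius: float          # scene-normalized units
    n_neighbors: int
    mlp: tuple             # shared-MLP widths


@dataclass
class ModelConfig:
    """Architecture toggles and shapes; all 8 toggle combinations are valid."""

    use_ms: bool = True
    use_se: bool = True
    use_gc: bool = True
    use_improved_fp: bool = True
    stages: tuple = (
        StageConfig(1024, 0.1, 32, (64, 64)),
        StageConfig(256, 0.2, 32, (128, 128)),
        StageConfig(64, 0.4, 32, (256, 256)),
        StageConfig(16, 0.8, 32, (512, 512)),
    )
    fp_channels: tuple = (256, 256, 128, 128)
    se_reduction: int = 4
    gc_reduction: int = 4
    n_classes: int = 3
    use_colors: bool = False
    seed: int = 0

    def validate(self) -> "ModelConfig":
        counts = [s.n_points for s in self.stages]
        if any(a <= b for a, b in zip(counts, counts[1:])):
            raise ValueError("stage point counts must be strictly decreasing")
        if self.se_reduction <= 1 or self.gc_reduction <= 1:
            raise ValueError("compression ratios must exceed 1")
        if len(self.fp_channels) != len(self.stages):
            raise ValueError("need one FP stage per encoder stage")
        return self

    @property
    def in_channels(self) -> int:
        return 9 if self.use_colors else 6

    @classmethod
    def compact(cls, **overrides) -> "ModelConfig":
        """Small configuration for CPU-scale experiments."""
        base = cls(
            stages=(
                StageConfig(512, 0.1, 16, (32, 32)),
                StageConfig(128, 0.25, 16, (64, 64)),
                StageConfig(32, 0.6, 8, (128, 128)),
            ),
            fp_channels=(64, 48, 32),
        )
        return replace(base, **overrides)


def ablation_grid() -> dict:
    """The 8 toggle combinations of the MS / SE / GC ablation.

    The improved feature-propagation layer is built from multi-scale
    residual blocks, so it follows the MS toggle.
    """
    rows = (
        ("Baseline", False, False, False),
        ("+MS", True, False, False),
        ("+SE Block", False, True, False),
        ("+GC", False, False, True),
        ("+MS+SE Block", True, True, False),
        ("+MS+GC", True, False, True),
        ("+GC+SE Block", False, True, True),
        ("Full_model", True, True, True),
    )
    return {
        name: dict(use_ms=ms, use_se=se, use_gc=gc, use_improved_fp=ms)
        for name, ms, se, gc in rows
    }


@dataclass
class FeatureMap:
    """Point coordinates plus a per-point feature matrix."""

    coords: np.ndarray
    features: Tensor


# ----------------------------------------------------------------------
# sampling and grouping (index computations, gradient-free)
# ----------------------------------------------------------------------

def farthest_point_sampling(coords: np.ndarray, m: int, start: int = 0) -> np.ndarray:
    """Deterministic FPS indices (first index = ``start``)."""
    coords = np.asarray(coords, dtype=np.float64)
    n = coords.shape[0]
    m = min(m, n)
    idx = np.empty(m, dtype=np.int64)
    idx[0] = start
    dist = np.linalg.norm(coords - coords[start], axis=1)
    for i in range(1, m):
        idx[i] = int(np.argmax(dist))
        d = np.linalg.norm(coords - coords[idx[i]], axis=1)
        np.minimum(dist, d, out=dist)
    return idx


def ball_group(coords: np.ndarray, centers: np.ndarray, radius: float,
               k: int) -> np.ndarray:
    """Indices (M, K) of up to ``k`` nearest neighbors within ``radius``.

    Centers with fewer than ``k`` in-radius neighbors repeat their nearest
    neighbor, the standard grouping convention.
    """
    tree = cKDTree(coords)
    k_eff = min(k, coords.shape[0])
    dist, idx = tree.query(centers, k=k_eff)
    if k_eff == 1:
        dist, idx = dist[:, None], idx[:, None]
    out = np.where(dist <= radius, idx, idx[:, :1])
    if k_eff < k:
        out = np.concatenate([out] + [out[:, :1]] * (k - k_eff), axis=1)
    return out.astype(np.int64)


def interpolation_plan(coords_low: np.ndarray, coords_high: np.ndarray,
                       k: int = 3):
    """k-NN inverse-square-distance weights for feature upsampling.

    A query coinciding with a source point (distance < 1e-10) copies that
    source's feature exactly.
    """
    k_eff = min(k, coords_low.shape[0])
    tree = cKDTree(coords_low)
    dist, idx = tree.query(coords_high, k=k_eff)
    if k_eff == 1:
        dist, idx = dist[:, None], idx[:, None]
    w = 1.0 / np.maximum(dist, 1e-10) ** 2
    exact = dist[:, 0] < 1e-10
    w[exact] = 0.0
    w[exact, 0] = 1.0
    w = w / w.sum(axis=1, keepdims=True)
    return idx.astype(np.int64), w


def interpolate_features(coords_low, feats_low, coords_high, k: int = 3):
    """Functional k-NN inverse-distance interpolation (numpy in/out)."""
    if np.asarray(coords_low).shape[0] == 0:
        raise ValueError("source set is empty")
    idx, w = interpolation_plan(np.asarray(coords_low), np.asarray(coords_high), k)
    feats_low = np.asarray(feats_low)
    return np.einsum("qk,qkc->qc", w, feats_low[idx])


@dataclass
class ScenePlan:
    """Per-scene sampling pyramid, reusable across epochs."""

    coords: list            # normalized coords per level, level 0 = input
    group_idx: list         # (M_i, K_i) into level i
    fp_idx: list            # per FP stage, indices into the lower level
    fp_w: list


def normalize_scene(coords: np.ndarray):
    """Center and scale to the unit sphere (per scene)."""
    center = coords.mean(axis=0)
    shifted = coords - center
    scale = float(np.linalg.norm(shifted, axis=1).max())
    scale = scale if scale > 0 else 1.0
    return shifted / scale, center, scale


def build_scene_plan(coords: np.ndarray, config: ModelConfig) -> ScenePlan:
    norm, _, _ = normalize_scene(np.asarray(coords, dtype=np.float64))
    level_coords = [norm]
    group_idx = []
    for stage in config.stages:
        prev = level_coords[-1]
        fps = farthest_point_sampling(prev, stage.n_points)
        centers = prev[fps]
        group_idx.append(ball_group(prev, centers, stage.radius, stage.n_neighbors))
        level_coords.append(centers)
    fp_idx, fp_w = [], []
    for level in range(len(config.stages), 0, -1):
        idx, w = interpolation_plan(level_coords[level], level_coords[level - 1])
        fp_idx.append(idx)
        fp_w.append(w)
    return ScenePlan(level_coords, group_idx, fp_idx, fp_w)


def stack_plans(plans) -> ScenePlan:
    """Stack per-scene plans into batched index arrays."""
    return ScenePlan(
        coords=[np.stack(c) for c in zip(*(p.coords for p in plans))],
        group_idx=[np.stack(g) for g in zip(*(p.group_idx for p in plans))],
        fp_idx=[np.stack(i) for i in zip(*(p.fp_idx for p in plans))],
        fp_w=[np.stack(w) for w in zip(*(p.fp_w for p in plans))],
    )


# ----------------------------------------------------------------------
# building blocks
# ----------------------------------------------------------------------

#: dtype for model weights and activations; float32 keeps training fast
MODEL_DTYPE = np.float32


def _weight(rng, cin, cout, gain=2.0):
    """He-style init; ``gain`` 2 for ReLU-followed layers, ~1 otherwise."""
    return Tensor(rng.normal(0.0, np.sqrt(gain / cin), (cin, cout)).astype(MODEL_DTYPE),
                  requires_grad=True)


class Linear:
    """Shared (pointwise) fully connected layer, i.e. a 1x1 convolution."""

    def __init__(self, rng, cin, cout, bias=True, gain=2.0):
        self.W = _weight(rng, cin, cout, gain)
        self.b = (Tensor(np.zeros(cout, MODEL_DTYPE), requires_grad=True)
                  if bias else None)

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.W
        return out + self.b if self.b is not None else out

    def parameters(self):
        return [self.W] + ([self.b] if self.b is not None else [])


class Conv1dLayer:
    """1D convolution along the canonical point ordering."""

    def __init__(self, rng, k, cin, cout, gain=1.0):
        self.w = Tensor(
            rng.normal(0.0, np.sqrt(gain / (k * cin)), (k, cin, cout)).astype(MODEL_DTYPE),
            requires_grad=True,
        )
        self.b = Tensor(np.zeros(cout, MODEL_DTYPE), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        k = self.w.shape[0]
        m = x.shape[-2]
        if m < k:
            # reflective-extension fallback for very short sequences
            idx = np.pad(np.arange(m), (k // 2, k // 2), mode="reflect" if m > 1 else "edge")
            batch = x.shape[:-2]
            idx_b = np.broadcast_to(idx, batch + idx.shape)
            ext = gather_points(x, idx_b)
            out = conv1d(ext, self.w, self.b)
            center = np.broadcast_to(
                np.arange(k // 2, k // 2 + m), batch + (m,)
            )
            return gather_points(out, center)
        return conv1d(x, self.w, self.b)

    def parameters(self):
        return [self.w, self.b]


class MultiScaleConv:
    """Parallel kernel-1/3/5 convolutions fused by a 1x1 convolution."""

    def __init__(self, rng, cin, cout, branch=None):
        branch = branch or cout
        self.branches = [Conv1dLayer(rng, k, cin, branch) for k in (1, 3, 5)]
        # sub-unit gain keeps the residual main branch small at init
        self.fuse = Linear(rng, 3 * branch, cout, gain=0.5)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fuse(concat([br(x) for br in self.branches], axis=-1))

    def parameters(self):
        out = []
        for br in self.branches:
            out += br.parameters()
        return out + self.fuse.parameters()


class SEBlock:
    """Squeeze-and-excitation channel attention.

    ``s = sigmoid(W2 relu(W1 z))`` with ``z`` the per-channel mean over
    points; output is the channel-wise rescaled input.  With zero weights
    the block is an exact half-scaling (sigmoid(0) = 0.5).
    """

    def __init__(self, rng, c, reduction=4):
        hidden = max(1, c // reduction)
        self.W1 = _weight(rng, c, hidden, gain=2.0)
        self.W2 = _weight(rng, hidden, c, gain=1.0)

    def __call__(self, x: Tensor) -> Tensor:
        z = x.mean(axis=-2)                     # (..., C)
        s = ((z @ self.W1).relu() @ self.W2).sigmoid()
        s = s.reshape(*s.shape[:-1], 1, s.shape[-1])
        return x * s

    def parameters(self):
        return [self.W1, self.W2]


class GlobalContext:
    """Broadcast-added bottlenecked scene descriptor.

    ``out = F + broadcast(Wu relu(Wd g))`` with ``g`` the mean feature over
    all points; with zero ``Wu`` the module is an exact identity, and the
    pooled descriptor is invariant to point permutation.
    """

    def __init__(self, rng, c, reduction=4):
        hidden = max(1, c // reduction)
        self.Wd = _weight(rng, c, hidden, gain=2.0)
        self.Wu = _weight(rng, hidden, c, gain=1.0)

    def __call__(self, x: Tensor) -> Tensor:
        g = x.mean(axis=-2)
        u = (g @ self.Wd).relu() @ self.Wu
        u = u.reshape(*u.shape[:-1], 1, u.shape[-1])
        return x + u

    def parameters(self):
        return [self.Wd, self.Wu]


class MSResBlock:
    """Residual wrapper around multi-scale convolution (+ optional SE).

    The shortcut is an identity when channel counts match, else a learned
    1x1 projection.
    """

    def __init__(self, rng, cin, cout, use_se=False, se_reduction=4):
        self.ms = MultiScaleConv(rng, cin, cout)
        self.se = SEBlock(rng, cout, se_reduction) if use_se else None
        self.proj = (None if cin == cout
                     else Linear(rng, cin, cout, bias=False, gain=1.0))

    def __call__(self, x: Tensor) -> Tensor:
        main = self.ms(x)
        if self.se is not None:
            main = self.se(main)
        shortcut = x if self.proj is None else self.proj(x)
        return main + shortcut

    def parameters(self):
        out = self.ms.parameters()
        if self.se is not None:
            out += self.se.parameters()
        if self.proj is not None:
            out += self.proj.parameters()
        return out


def residual_wrap(x: Tensor, main_branch, proj=None) -> Tensor:
    """Generic residual connection: ``main_branch(x) + shortcut(x)``."""
    shortcut = x if proj is None else proj(x)
    return main_branch(x) + shortcut


class SetAbstraction:
    """Sample centers, group in-radius neighbors, encode, max-pool."""

    def __init__(self, rng, cin, stage: StageConfig):
        widths = [cin + 3] + list(stage.mlp)
        self.layers = [Linear(rng, a, b) for a, b in zip(widths, widths[1:])]
        self.stage = stage

    def __call__(self, coords_prev, coords_ctr, group_idx, feats: Tensor) -> Tensor:
        grouped = gather_points(feats, group_idx)          # (B, M, K, C)
        batched = coords_prev[
            np.arange(coords_prev.shape[0])[:, None, None], group_idx
        ]
        rel = (batched - coords_ctr[:, :, None, :]) / self.stage.radius
        h = concat([Tensor(rel.astype(grouped.data.dtype)), grouped], axis=-1)
        for layer in self.layers:
            h = layer(h).relu()
        return h.max(axis=-2)

    def parameters(self):
        return [p for layer in self.layers for p in layer.parameters()]


class FeaturePropagation:
    """Upsample, fuse with the skip connection, refine, map to C_out."""

    def __init__(self, rng, c_low, c_skip, cout, improved, use_se, se_reduction):
        cin = c_low + c_skip
        self.improved = improved
        if improved:
            self.block = MSResBlock(rng, cin, cout, use_se, se_reduction)
            self.final = Linear(rng, cout, cout, gain=1.0)
        else:
            self.mlp = [Linear(rng, cin, cout), Linear(rng, cout, cout)]

    def __call__(self, feats_low: Tensor, skip: Tensor, idx, w) -> Tensor:
        gathered = gather_points(feats_low, idx)           # (B, Nh, k, C)
        wt = Tensor(w[..., None].astype(gathered.data.dtype))
        interp = (gathered * wt).sum(axis=-2)
        fused = concat([interp, skip], axis=-1)
        if self.improved:
            return self.final(self.block(fused))
        h = fused
        for layer in self.mlp:
            h = layer(h).relu()
        return h

    def parameters(self):
        if self.improved:
            return self.block.parameters() + self.final.parameters()
        return [p for layer in self.mlp for p in layer.parameters()]


# ----------------------------------------------------------------------
# the full model
# ----------------------------------------------------------------------

class SegmentationModel:
    """Encoder/decoder semantic segmentation network with ablation toggles."""

    def __init__(self, config: ModelConfig):
        self.config = config.validate()
        rng = np.random.default_rng(config.seed)
        cin = config.in_channels
        self.sa_stages, self.ms_blocks, self.se_standalone = [], [], []
        c = cin
        for stage in config.stages:
            sa = SetAbstraction(rng, c, stage)
            self.sa_stages.append(sa)
            c = stage.mlp[-1]
            if config.use_ms:
                self.ms_blocks.append(
                    MSResBlock(rng, c, c, config.use_se, config.se_reduction)
                )
                self.se_standalone.append(None)
            else:
                self.ms_blocks.append(None)
                self.se_standalone.append(
                    SEBlock(rng, c, config.se_reduction) if config.use_se else None
                )
        # decoder: deepest level back to the input level
        skip_channels = [cin] + [s.mlp[-1] for s in config.stages[:-1]]
        self.fp_stages = []
        c_low = config.stages[-1].mlp[-1]
        for level in range(len(config.stages) - 1, -1, -1):
            cout = config.fp_channels[len(config.stages) - 1 - level]
            self.fp_stages.append(
                FeaturePropagation(
                    rng, c_low, skip_channels[level], cout,
                    config.use_improved_fp, config.use_se, config.se_reduction,
                )
            )
            c_low = cout
        self.gc = (
            GlobalContext(rng, c_low, config.gc_reduction)
            if config.use_gc else None
        )
        self.head = [Linear(rng, c_low, c_low),
                     Linear(rng, c_low, config.n_classes, gain=1.0)]

    # ------------------------------------------------------------------
    def parameters(self):
        out = []
        for sa in self.sa_stages:
            out += sa.parameters()
        for block in self.ms_blocks:
            if block is not None:
                out += block.parameters()
        for se in self.se_standalone:
            if se is not None:
                out += se.parameters()
        for fp in self.fp_stages:
            out += fp.parameters()
        if self.gc is not None:
            out += self.gc.parameters()
        for layer in self.head:
            out += layer.parameters()
        return out

    @property
    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    # ------------------------------------------------------------------
    def features_from_cloud(self, coords, normals, colors=None) -> np.ndarray:
        """Input features: scene-centered xyz + unit normals (+ rgb/255)."""
        norm, _, _ = normalize_scene(np.asarray(coords, dtype=np.float64))
        feats = [norm, np.asarray(normals, dtype=np.float64)]
        if self.config.use_colors:
            feats.append(np.asarray(colors, dtype=np.float64) / 255.0)
        return np.concatenate(feats, axis=1).astype(MODEL_DTYPE)

    def forward(self, plan: ScenePlan, features: np.ndarray) -> Tensor:
        """Batched forward pass: features (B, N, C) -> logits (B, N, K)."""
        h = Tensor(features)
        skips = [h]
        for i, sa in enumerate(self.sa_stages):
            h = sa(plan.coords[i], plan.coords[i + 1], plan.group_idx[i], h)
            if self.ms_blocks[i] is not None:
                h = self.ms_blocks[i](h)
            elif self.se_standalone[i] is not None:
                h = self.se_standalone[i](h)
            skips.append(h)
        for j, fp in enumerate(self.fp_stages):
            level = len(self.sa_stages) - 1 - j
            h = fp(h, skips[level], plan.fp_idx[j], plan.fp_w[j])
        if self.gc is not None:
            h = self.gc(h)
        h = self.head[0](h).relu()
        return self.head[1](h)

    def predict_scene(self, coords, normals, colors=None) -> np.ndarray:
        """Per-point class labels for a single scene."""
        plan = stack_plans([build_scene_plan(coords, self.config)])
        feats = self.features_from_cloud(coords, normals, colors)[None]
        logits = self.forward(plan, feats)
        return np.argmax(logits.data[0], axis=-1)


def build_model(config: ModelConfig) -> SegmentationModel:
    return SegmentationModel(config)


# ----------------------------------------------------------------------
# loss
# ----------------------------------------------------------------------

def cross_entropy(logits, labels) -> Tensor:
    """Mean negative log-softmax of the true class.

    ``logits``: Tensor or array (..., N, K); ``labels``: integer array
    (..., N) with values in [0, K).
    """
    t = logits if isinstance(logits, Tensor) else Tensor(logits)
    k = t.shape[-1]
    labels = np.asarray(labels)
    if labels.min() < 0 or labels.max() >= k:
        raise ValueError("labels out of range")
    onehot = np.eye(k, dtype=t.data.dtype)[labels]
    n = labels.size
    return (t.log_softmax() * Tensor(onehot)).sum() * (-1.0 / n)


def approx_flops(config: ModelConfig, n_points: int = 2049) -> int:
    """Rough multiply-add count of one forward pass (informational only)."""
    total = 0
    n_prev, c = n_points, config.in_channels
    for stage in config.stages:
        widths = [c + 3] + list(stage.mlp)
        per_point = sum(a * b for a, b in zip(widths, widths[1:]))
        total += stage.n_points * stage.n_neighbors * per_point
        c = stage.mlp[-1]
        if config.use_ms:
            total += stage.n_points * (9 * c * c + 3 * c * c)
        n_prev = stage.n_points
    c_low = c
    skip = [config.in_channels] + [s.mlp[-1] for s in config.stages[:-1]]
    counts = [n_points] + [s.n_points for s in config.stages[:-1]]
    for j, cout in enumerate(config.fp_channels):
        level = len(config.stages) - 1 - j
        cin = c_low + skip[level]
        mult = 12 if config.use_improved_fp else 2
        total += counts[level] * mult * cin * cout
        c_low = cout
    total += n_points * (c_low * c_low + c_low * config.n_classes)
    return int(total)
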