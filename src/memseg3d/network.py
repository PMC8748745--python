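"""Light-weight 3D semantic segmentation network and its training loop.

The architecture is a shallow U-Net: a few encoder levels with residual
strided-convolution downsampling, a decoder with nearest-neighbor
upsampling, and skip concatenations. After each upsampling, extra voxels on
the high-index edge of the feature map are trimmed so it exactly matches
the corresponding encoder map — this is what lets the network process
cuboid inputs of any size, cubic or not, and guarantees output extent ==
input extent. The head is a 1x1x1 convolution to 3 channels followed by a
softmax, so per-voxel class probabilities sum to 1.

Training samples cuboids of slightly varying extents at random origins from
the training volumes (variable-size cuboid training improves behavior at
cuboid interfaces), accumulates the analytic loss gradient over a batch,
and updates with Adam. Everything is plain numpy; determinism for a fixed
seed holds on a single device.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Iterator, Optional, Sequence

import numpy as np

from . import loss as L
from .nn import (Adam, Conv3d, relu, relu_backward, softmax_backward,
                 softmax_channels, trim_backward, trim_to, upsample2,
                 upsample2_backward)
from .phantom import SemanticMasks, semantic_masks_from_labels
from .volume_io import IntensityVolume, LabelVolume, TileLayout, plan_tiles, \
    stitch_probability_tiles

__all__ = [
    "NetworkConfig",
    "TrainConfig",
    "TrainingLog",
    "SegNet3D",
    "build_network",
    "sample_training_cuboids",
    "train_semantic_model",
    "predict_semantic_volume",
    "semantic_argmax",
    "TrainingDivergence",
]


class TrainingDivergence(RuntimeError):
    """Raised when the training loss becomes non-finite."""


@dataclasses.dataclass
class NetworkConfig:
    """Architecture knobs; defaults give ~0.35 M parameters (~1.4 MB)."""

    n_levels: int = 3
    base_channels: int = 16
    channel_growth: int = 2
    residual_downsampling: bool = True
    parameter_budget: int = 1_500_000

    def channels(self) -> list[int]:
        return [self.base_channels * self.channel_growth**i for i in range(self.n_levels)]


@dataclasses.dataclass
class TrainConfig:
    """Optimization settings.

    Cuboid extents default to the 56^3..64^3 range; Adam with batch 7.
    ``alpha`` is the confidence-replacement constant, ``w_min`` the interior
    floor of the reverse-distance weights, ``mask_thickness`` the membrane
    thickness used when deriving semantic masks from instance labels.
    """

    cuboid_min: tuple[int, int, int] = (56, 56, 56)
    cuboid_max: tuple[int, int, int] = (64, 64, 64)
    batch_size: int = 7
    learning_rate: float = 1e-3
    steps: int = 500
    seed: int = 0
    alpha: float = 0.1
    w_min: float = 0.5
    mask_thickness: float = 2.0
    context_pad: int = 8
    plain_dice: bool = False
    use_weights: bool = True

    def __post_init__(self) -> None:
        self.cuboid_min = tuple(int(v) for v in self.cuboid_min)
        self.cuboid_max = tuple(int(v) for v in self.cuboid_max)
        if any(a > b for a, b in zip(self.cuboid_min, self.cuboid_max)):
            raise ValueError("cuboid_min must be <= cuboid_max elementwise")


@dataclasses.dataclass
class TrainingLog:
    """Per-step loss breakdowns plus the configuration snapshot."""

    steps: list[dict] = dataclasses.field(default_factory=list)
    config: dict = dataclasses.field(default_factory=dict)

    def totals(self) -> np.ndarray:
        return np.array([s["total"] for s in self.steps])

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self))


class SegNet3D:
    """The network: encoder/decoder layer stacks with explicit backprop."""

    def __init__(self, cfg: NetworkConfig | None = None, seed: int = 0):
        self.cfg = cfg or NetworkConfig()
        rng = np.random.default_rng(seed)
        ch = self.cfg.channels()
        self.enc_a: list[Conv3d] = []   # first conv of each level (stride 2 past level 0)
        self.enc_proj: list[Optional[Conv3d]] = []  # 1x1 residual projection for downsampling
        self.enc_b: list[Conv3d] = []   # second conv of each level
        for i, c in enumerate(ch):
            cin = 1 if i == 0 else ch[i - 1]
            stride = 1 if i == 0 else 2
            self.enc_a.append(Conv3d(cin, c, k=3, stride=stride, rng=rng))
            if i > 0 and self.cfg.residual_downsampling:
                self.enc_proj.append(Conv3d(cin, c, k=1, stride=2, rng=rng))
            else:
                self.enc_proj.append(None)
            self.enc_b.append(Conv3d(c, c, k=3, stride=1, rng=rng))
        self.dec_up: list[Conv3d] = []   # conv after nearest-neighbor upsampling
        self.dec_fuse: list[Conv3d] = []  # conv after skip concatenation
        for i in range(self.cfg.n_levels - 2, -1, -1):
            self.dec_up.append(Conv3d(ch[i + 1], ch[i], k=3, stride=1, rng=rng))
            self.dec_fuse.append(Conv3d(2 * ch[i], ch[i], k=3, stride=1, rng=rng))
        self.head = Conv3d(ch[0], 3, k=1, stride=1, rng=rng)
        self._cache: dict | None = None
        if self.n_parameters > self.cfg.parameter_budget:
            import warnings

            warnings.warn(
                f"network has {self.n_parameters} parameters, over the "
                f"budget of {self.cfg.parameter_budget}",
                stacklevel=2,
            )

    # -- parameter plumbing -------------------------------------------------
    def layers(self) -> list[Conv3d]:
        out = []
        for a, p, b in zip(self.enc_a, self.enc_proj, self.enc_b):
            out.extend([a] + ([p] if p is not None else []) + [b])
        for u, f in zip(self.dec_up, self.dec_fuse):
            out.extend([u, f])
        out.append(self.head)
        return out

    @property
    def n_parameters(self) -> int:
        return sum(l.n_parameters for l in self.layers())

    def zero_grad(self) -> None:
        for l in self.layers():
            l.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {}
        for i, l in enumerate(self.layers()):
            out[f"W{i}"] = l.W.copy()
            out[f"b{i}"] = l.b.copy()
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, l in enumerate(self.layers()):
            l.W[...] = state[f"W{i}"]
            l.b[...] = state[f"b{i}"]

    def save(self, path) -> None:
        meta = json.dumps(dataclasses.asdict(self.cfg))
        np.savez(path, __config__=np.frombuffer(meta.encode(), dtype=np.uint8),
                 **self.state_dict())

    @classmethod
    def load(cls, path) -> "SegNet3D":
        with np.load(path) as f:
            cfg = NetworkConfig(**json.loads(bytes(f["__config__"]).decode()))
            net = cls(cfg)
            net.load_state_dict({k: f[k] for k in f.files if k != "__config__"})
        return net

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Input (Z, Y, X) intensities -> (3, Z, Y, X) class probabilities."""
        if x.ndim != 3:
            raise ValueError(f"expected a (Z, Y, X) volume, got shape {x.shape}")
        h = x[None].astype(np.float32)
        cache: dict = {"skips": [], "acts": []}
        skips = []
        for i in range(self.cfg.n_levels):
            a = self.enc_a[i].forward(h, train)
            if self.enc_proj[i] is not None:
                a = a + self.enc_proj[i].forward(h, train)
            a = relu(a)
            b = relu(self.enc_b[i].forward(a, train))
            cache["acts"].append((a, b))
            skips.append(b)
            h = b
        for j, i in enumerate(range(self.cfg.n_levels - 2, -1, -1)):
            up = upsample2(h)
            u = relu(self.dec_up[j].forward(up, train))
            skip = skips[i]
            ut = trim_to(u, skip.shape[1:])
            cat = np.concatenate([ut, skip], axis=0)
            h = relu(self.dec_fuse[j].forward(cat, train))
            cache["acts"].append((up.shape, u, h, skip.shape[1:]))
        logits = self.head.forward(h, train)
        probs = softmax_channels(logits)
        if train:
            cache["probs"] = probs
            self._cache = cache
        return probs

    def backward(self, dprobs: np.ndarray) -> None:
        """Backpropagate a gradient w.r.t. the output probabilities."""
        cache = self._cache
        self._cache = None
        probs = cache["probs"]
        dh = self.head.backward(softmax_backward(dprobs, probs).astype(np.float32))
        nl = self.cfg.n_levels
        dskips: list[np.ndarray | None] = [None] * nl
        for j in range(nl - 2, -1, -1):  # decoder stages in reverse
            up_shape, u, hout, skip_shape = cache["acts"][nl + j]
            i = nl - 2 - j
            dcat = self.dec_fuse[j].backward(relu_backward(dh, hout))
            c = u.shape[0]
            dut, dskip = dcat[:c], dcat[c:]
            if dskips[i] is None:
                dskips[i] = dskip
            else:
                dskips[i] = dskips[i] + dskip
            du = trim_backward(dut, u.shape[1:])
            dup = self.dec_up[j].backward(relu_backward(du, u))
            dh = upsample2_backward(dup)
        # dh is now the gradient into the deepest encoder output
        dskips[nl - 1] = dh
        dx = None
        for i in range(nl - 1, -1, -1):
            a, b = cache["acts"][i]
            db = dskips[i]
            if i < nl - 1 and dx is not None:
                db = db + dx
            da = self.enc_b[i].backward(relu_backward(db, b))
            da = relu_backward(da, a)
            dx = self.enc_a[i].backward(da)
            if self.enc_proj[i] is not None:
                dx = dx + self.enc_proj[i].backward(da)


def build_network(cfg: NetworkConfig | None = None, seed: int = 0) -> SegNet3D:
    """Construct the network; warns (does not fail) over the parameter budget."""
    return SegNet3D(cfg, seed=seed)


def _reflect_pad_to(arr: np.ndarray, minimum: Sequence[int]) -> np.ndarray:
    pads = [(0, max(0, m - s)) for m, s in zip(minimum, arr.shape[-3:])]
    if arr.ndim == 4:
        pads = [(0, 0)] + pads
    if any(p[1] for p in pads):
        return np.pad(arr, pads, mode="reflect")
    return arr


def sample_training_cuboids(
    image: IntensityVolume | np.ndarray,
    masks: SemanticMasks,
    weights: np.ndarray | None,
    cfg: TrainConfig,
    seed: int | None = None,
) -> Iterator[tuple[np.ndarray, np.ndarray, np.ndarray | None]]:
    """Endless stream of (x, g, w) training cuboids.

    Each draw picks a uniform random extent per axis in
    [cuboid_min, cuboid_max] and a uniform random origin. Volumes smaller
    than cuboid_min are reflect-padded first. Deterministic for fixed seed.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    x = image.data if isinstance(image, IntensityVolume) else np.asarray(image)
    g = masks.stack()
    x = _reflect_pad_to(x, cfg.cuboid_min)
    g = _reflect_pad_to(g, cfg.cuboid_min)
    w = None if weights is None else _reflect_pad_to(np.asarray(weights), cfg.cuboid_min)
    shape = x.shape
    while True:
        ext = [int(rng.integers(cfg.cuboid_min[a], min(cfg.cuboid_max[a], shape[a]) + 1))
               for a in range(3)]
        org = [int(rng.integers(0, shape[a] - ext[a] + 1)) for a in range(3)]
        box = tuple(slice(org[a], org[a] + ext[a]) for a in range(3))
        yield (
            x[box],
            g[(slice(None),) + box],
            None if w is None else w[(slice(None),) + box],
        )


def train_semantic_model(
    dataset: Sequence[tuple[IntensityVolume, LabelVolume]],
    cfg: TrainConfig | None = None,
    net_cfg: NetworkConfig | None = None,
    init: SegNet3D | None = None,
) -> tuple[SegNet3D, TrainingLog]:
    """Train the semantic network on (intensity, instance-label) pairs.

    Masks and reverse-distance weights are derived from the labels. Passing
    ``init`` warm-starts from existing parameters (fine-tuning); with
    ``cfg.steps == 0`` the parameters are returned unchanged.
    """
    cfg = cfg or TrainConfig()
    if not dataset:
        raise ValueError("training requires at least one (image, labels) pair")
    net = init if init is not None else SegNet3D(net_cfg, seed=cfg.seed)
    log = TrainingLog(config={"train": dataclasses.asdict(cfg),
                              "network": dataclasses.asdict(net.cfg)})
    if cfg.steps == 0:
        return net, log

    samplers = []
    for i, (image, labels) in enumerate(dataset):
        # represent the empty space outside the imaged volume by zeros, so
        # volume-edge voxels are trained with the same context they will
        # have under the padded inference scheme (see predict_semantic_volume)
        x = image.data if isinstance(image, IntensityVolume) else np.asarray(image)
        lab = labels.labels if isinstance(labels, LabelVolume) else np.asarray(labels)
        if cfg.context_pad > 0:
            x = np.pad(x, cfg.context_pad)
            lab = np.pad(lab, cfg.context_pad)
        masks = semantic_masks_from_labels(lab, cfg.mask_thickness)
        weights = L.weight_stack(masks, cfg.w_min) if cfg.use_weights else None
        samplers.append(
            sample_training_cuboids(x, masks, weights, cfg, seed=cfg.seed + 7919 * i)
        )
    opt = Adam(net.layers(), lr=cfg.learning_rate)
    for step in range(cfg.steps):
        net.zero_grad()
        tot = fg = oth = 0.0
        for b in range(cfg.batch_size):
            x, g, w = next(samplers[(step * cfg.batch_size + b) % len(samplers)])
            probs = net.forward(x, train=True)
            br = L.total_loss(probs, g, w, cfg.alpha, plain_dice=cfg.plain_dice)
            grad = L.loss_gradient(probs, g, w, cfg.alpha, plain_dice=cfg.plain_dice)
            net.backward(grad / cfg.batch_size)
            tot += br.total / cfg.batch_size
            fg += br.foreground_term / cfg.batch_size
            oth += br.others_term / cfg.batch_size
        if not np.isfinite(tot):
            raise TrainingDivergence(f"non-finite loss at step {step}")
        opt.step()
        log.steps.append({"step": step, "total": tot, "foreground": fg, "others": oth})
    return net, log


def predict_semantic_volume(
    image: IntensityVolume | np.ndarray,
    net: SegNet3D,
    layout: TileLayout | None = None,
    tile_extent: Sequence[int] = (64, 64, 64),
    overlap: Sequence[int] = (8, 8, 8),
    context_pad: int = 8,
) -> L.ClassProbabilityVolume:
    """Tiled inference over a full volume; cores stitched seam-free.

    The volume is first zero-padded by ``context_pad`` voxels per side —
    zeros represent the empty space outside the imaged region, and the
    padding gives volume-edge voxels the same spatial context the network
    saw during training. The padded margin is cropped from the output, so
    the result matches the input extent. ``context_pad=0`` disables this
    (a single tile then reduces to a direct forward pass). An explicit
    ``layout`` must be planned for the padded extent.
    """
    x = image.data if isinstance(image, IntensityVolume) else np.asarray(image)
    xp = np.pad(x, context_pad) if context_pad > 0 else x
    minimum = 2 ** (net.cfg.n_levels - 1)
    xp = _reflect_pad_to(xp, (minimum,) * 3)
    if layout is None:
        layout = plan_tiles(xp.shape, tile_extent, overlap)
    tiles = []
    for origin, _core in layout.tiles:
        ext = tuple(min(layout.tile_extent[a], layout.extent[a] - origin[a]) for a in range(3))
        box = tuple(slice(origin[a], origin[a] + ext[a]) for a in range(3))
        tiles.append(net.forward(xp[box], train=False))
    probs = stitch_probability_tiles(layout, tiles)
    probs = probs[
        :,
        context_pad : context_pad + x.shape[0],
        context_pad : context_pad + x.shape[1],
        context_pad : context_pad + x.shape[2],
    ]
    return L.ClassProbabilityVolume(np.ascontiguousarray(probs))


def semantic_argmax(probs: L.ClassProbabilityVolume | np.ndarray) -> SemanticMasks:
    """Per-voxel argmax with tie priority foreground > membrane > background."""
    p = probs.probs if isinstance(probs, L.ClassProbabilityVolume) else np.asarray(probs)
    # argmax returns the first maximum; order channels by descending priority
    prio = np.argmax(p[[L.FOREGROUND, L.MEMBRANE, L.BACKGROUND]], axis=0)
    return SemanticMasks(background=prio == 2, membrane=prio == 1, foreground=prio == 0)
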