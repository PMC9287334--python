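"""The multi-plane orbital classifier: configuration, construction, forward.

Each configured plane owns an independent branch:

    input (32 slices as channels)
      -> 3x3 conv (32 -> 16 or 32 ch) -> ReLU -> 2x2 max-pool
      -> 3x3 depthwise conv (standard conv in stage1) -> ReLU -> 2x2 max-pool
      -> binocular half-depthwise comparison -> (16 left, 16 right) -> ReLU
      -> flatten (32) -> fully connected (4) -> ReLU

and the concatenated per-plane embeddings feed a single head: one sigmoid
node for binary tasks, three softmax nodes for the 3-class task.  With the
default channel counts the post-layer-2 maps are axial 32x32x16, coronal
16x32x16 and sagittal 32x32x32 (height x width x channels) — the sagittal
map keeps 32 channels because each sagittal slice holds only one orbit and
the binocular split happens along the slice axis instead.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ..preprocessing import PlaneSet
from .comparison import STAGES, HalfComparison
from .layers import (Conv3x3, Dense, DepthwiseConv3x3, MaxPool2x2, Param,
                     ReLU, sigmoid, softmax)

PLANE_ORDER = ("axial", "coronal", "sagittal")

#: network input shapes, (height, width, slices)
INPUT_SHAPES = {"axial": (128, 128, 32), "coronal": (64, 128, 32),
                "sagittal": (128, 128, 32)}

#: orbit-separating axis per plane
SPLIT_MODES = {"axial": "spatial", "coronal": "spatial", "sagittal": "channel"}


@dataclass
class ModelConfig:
    planes: tuple[str, ...] = PLANE_ORDER
    stage: str = "proposed"
    n_classes: int = 2
    conv1_out_channels: dict[str, int] = field(
        default_factory=lambda: {"axial": 16, "coronal": 16, "sagittal": 32})
    conv_kernel: tuple[int, int] = (3, 3)
    pool: tuple[int, int] = (2, 2)
    orbit_filters: int = 16
    fc_nodes_per_plane: int = 4
    activation: str = "relu"
    init: str = "xavier"
    mirror_right: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        self.planes = tuple(p for p in PLANE_ORDER if p in self.planes)
        if not self.planes:
            raise ValueError("planes must be a non-empty subset of "
                             f"{PLANE_ORDER}")
        if self.stage not in STAGES:
            raise ValueError(f"stage must be one of {STAGES}")
        if self.n_classes not in (2, 3):
            raise ValueError("n_classes must be 2 or 3")
        if self.fc_nodes_per_plane < 1:
            raise ValueError("fc_nodes_per_plane must be >= 1")
        if tuple(self.conv_kernel) != (3, 3) or tuple(self.pool) != (2, 2):
            raise ValueError("only 3x3 kernels with 2x2 pooling are supported")
        for plane in self.planes:
            c1 = self.conv1_out_channels[plane]
            per_side = c1 if SPLIT_MODES[plane] == "spatial" else c1 // 2
            if per_side != self.orbit_filters:
                raise ValueError(
                    f"{plane}: {c1} channels give {per_side} filters per orbit "
                    f"side, but orbit_filters={self.orbit_filters}")

    def feature_shape(self, plane: str) -> tuple[int, int, int]:
        """Post-layer-2 map (height, width, channels) for one plane."""
        h, w, _ = INPUT_SHAPES[plane]
        return h // 4, w // 4, self.conv1_out_channels[plane]


class Model:
    """A built network; layers stored per plane plus a shared head."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.branches: dict[str, dict] = {}
        for plane in config.planes:
            c1 = config.conv1_out_channels[plane]
            fh, fw, _ = config.feature_shape(plane)
            mode = SPLIT_MODES[plane]
            half_hw = (fh, fw // 2) if mode == "spatial" else (fh, fw)
            if config.stage == "stage1":
                layer2 = Conv3x3(c1, c1, rng)
            else:
                layer2 = DepthwiseConv3x3(c1, rng)
            self.branches[plane] = {
                "conv1": Conv3x3(32, c1, rng),
                "relu1": ReLU(), "pool1": MaxPool2x2(),
                "layer2": layer2,
                "relu2": ReLU(), "pool2": MaxPool2x2(),
                "compare": HalfComparison(mode, c1, half_hw, config.stage, rng,
                                          config.mirror_right),
                "relu3": ReLU(),
                "fc": Dense(2 * config.orbit_filters, config.fc_nodes_per_plane, rng),
                "relu4": ReLU(),
            }
        head_in = config.fc_nodes_per_plane * len(config.planes)
        head_out = 1 if config.n_classes == 2 else 3
        self.head = Dense(head_in, head_out, rng)

    # ------------------------------------------------------------------ params
    def params(self) -> list[Param]:
        out: list[Param] = []
        seen: set[int] = set()
        for plane in self.config.planes:
            for layer in self.branches[plane].values():
                for p in layer.params():
                    if id(p) not in seen:
                        seen.add(id(p))
                        out.append(p)
        out.extend(self.head.params())
        return out

    def parameter_count(self) -> int:
        return sum(p.size for p in self.params())

    def parameter_breakdown(self) -> dict[str, int]:
        """Unique trainable scalars per named layer (tied weights counted once)."""
        out: dict[str, int] = {}
        for plane in self.config.planes:
            for name, layer in self.branches[plane].items():
                seen: set[int] = set()
                n = 0
                for p in layer.params():
                    if id(p) not in seen:
                        seen.add(id(p))
                        n += p.size
                if n:
                    out[f"{plane}.{name}"] = n
        out["head"] = sum(p.size for p in self.head.params())
        return out

    # ----------------------------------------------------------------- forward
    def _check_input(self, plane: str, arr: np.ndarray) -> None:
        expected = INPUT_SHAPES[plane]
        if arr.shape[1:] != (expected[2], expected[0], expected[1]):
            raise ValueError(
                f"{plane}: expected input of shape (height, width, slices)="
                f"{expected}, got channels-first batch {arr.shape}")

    def forward_batch(self, batch: dict[str, np.ndarray],
                      train: bool = True) -> np.ndarray:
        """Logits for a channels-first batch {plane: (B, 32, H, W)}."""
        embeddings = []
        for plane in self.config.planes:
            x = batch[plane]
            self._check_input(plane, x)
            br = self.branches[plane]
            x = br["conv1"].forward(x, need_input_grad=False)
            x = br["relu1"].forward(x)
            x = br["pool1"].forward(x)
            x = br["layer2"].forward(x)
            x = br["relu2"].forward(x)
            x = br["pool2"].forward(x)
            x = br["compare"].forward(x)
            x = br["relu3"].forward(x)
            x = br["fc"].forward(x)
            x = br["relu4"].forward(x)
            embeddings.append(x)
        return self.head.forward(np.concatenate(embeddings, axis=1))

    def backward(self, dlogits: np.ndarray) -> None:
        dcat = self.head.backward(dlogits)
        k = self.config.fc_nodes_per_plane
        for i, plane in enumerate(self.config.planes):
            br = self.branches[plane]
            d = dcat[:, i * k : (i + 1) * k]
            d = br["relu4"].backward(d)
            d = br["fc"].backward(d)
            d = br["relu3"].backward(d)
            d = br["compare"].backward(d)
            d = br["pool2"].backward(d)
            d = br["relu2"].backward(d)
            d = br["layer2"].backward(d)
            if d is not None:
                d = br["pool1"].backward(d)
                d = br["relu1"].backward(d)
                br["conv1"].backward(d)

    def plane_embedding(self, batch: dict[str, np.ndarray], plane: str,
                        upto: str = "relu4") -> np.ndarray:
        """Per-plane activations before the head (for inspection and tests)."""
        br = self.branches[plane]
        x = batch[plane]
        self._check_input(plane, x)
        order = ("conv1", "relu1", "pool1", "layer2", "relu2", "pool2",
                 "compare", "relu3", "fc", "relu4")
        for name in order:
            layer = br[name]
            x = layer.forward(x) if name != "conv1" else layer.forward(x, False)
            if name == upto:
                return x
        return x

    def predict_proba(self, batch: dict[str, np.ndarray]) -> np.ndarray:
        """Class probabilities: (B,) sigmoid for binary, (B, 3) softmax for 3-class."""
        z = self.forward_batch(batch, train=False)
        if self.config.n_classes == 2:
            return sigmoid(z[:, 0])
        return softmax(z)

    # -------------------------------------------------------------- state dict
    def state_dict(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params()]

    def load_state_dict(self, values: list[np.ndarray]) -> None:
        for p, v in zip(self.params(), values, strict=True):
            p.value[...] = v


def planeset_batch(cases: Sequence[PlaneSet],
                   planes: Sequence[str]) -> dict[str, np.ndarray]:
    """Stack PlaneSets into channels-first float32 arrays per plane."""
    batch = {}
    for plane in planes:
        arrs = [ps.plane(plane).transpose(2, 0, 1) for ps in cases]
        batch[plane] = np.stack(arrs).astype(np.float32)
    return batch


def build_model(cfg: ModelConfig) -> Model:
    """Build (and Xavier-initialise) the network described by ``cfg``."""
    return Model(cfg)


def build_ablation(cfg: ModelConfig, stage: str) -> Model:
    """Build the ablation variant ``stage`` of the configured network."""
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; expected one of {STAGES}")
    from dataclasses import replace
    return Model(replace(cfg, stage=stage))


def forward(model: Model, ps: PlaneSet) -> np.ndarray:
    """Class scores for a single PlaneSet.

    Returns a scalar probability in (0, 1) for binary models, else a
    length-3 probability vector summing to one.
    """
    batch = planeset_batch([ps], model.config.planes)
    proba = model.predict_proba(batch)
    return float(proba[0]) if model.config.n_classes == 2 else proba[0]


def describe(model: Model) -> str:
    """Human-readable per-layer shape / parameter table."""
    cfg = model.config
    lines = [f"stage={cfg.stage} planes={','.join(cfg.planes)} "
             f"n_classes={cfg.n_classes} seed={cfg.seed}"]
    for plane in cfg.planes:
        fh, fw, c = cfg.feature_shape(plane)
        lines.append(f"  {plane}: input {INPUT_SHAPES[plane]} -> "
                     f"post-layer-2 ({fh}, {fw}, {c}) -> compare "
                     f"{cfg.orbit_filters}x2 -> fc {cfg.fc_nodes_per_plane}")
    for name, n in model.parameter_breakdown().items():
        lines.append(f"  {name}: {n} params")
    lines.append(f"  total: {model.parameter_count()} params")
    return "\n".join(lines)


def save_checkpoint(model: Model, path) -> None:
    """Single-file checkpoint: JSON config header + weight arrays."""
    from dataclasses import asdict
    header = json.dumps(asdict(model.config))
    arrays = {f"w{i}": v for i, v in enumerate(model.state_dict())}
    np.savez(path, __config__=np.frombuffer(header.encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(path) -> Model:
    with np.load(path) as data:
        header = json.loads(bytes(data["__config__"]).decode())
        header["planes"] = tuple(header["planes"])
        header["conv_kernel"] = tuple(header["conv_kernel"])
        header["pool"] = tuple(header["pool"])
        model = Model(ModelConfig(**header))
        n = len(model.params())
        model.load_state_dict([data[f"w{i}"] for i in range(n)])
    return model
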