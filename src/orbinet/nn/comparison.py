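"""The binocular comparison layer (layer 3) and its ablation variants.

After two conv + pool blocks each plane's feature map still separates the
two orbits: along the in-plane *width* for axial and coronal maps, along
the *channel* (slice) axis for sagittal maps, where every slice contains
a single orbit.  The comparison layer splits the map into the patient-left
and patient-right halves and reduces each half to one scalar per channel
with a filter whose spatial extent equals the whole half — a "half
depthwise" convolution.  With 16 channels per side this yields the 16 x 2
comparison nodes that are flattened to 32 values per plane.

Stages of the ablation ladder differ only in how the per-side filters are
tied:

========  =======================  =========================
stage     axial / coronal          sagittal
========  =======================  =========================
stage1    standard conv (mixes     standard conv per
          channels), shared        channel-half, shared
stage2    depthwise, shared        depthwise, one filter per
          across the two halves    channel (untied)
stage3    depthwise, shared        depthwise, tied across the
                                   left/right channel halves
proposed  depthwise, separate      depthwise, separate
          left / right filters     left / right filters
========  =======================  =========================

Ascending index along the left-right axis always runs patient-right ->
patient-left, so the low half is the patient's right orbit.  With
``mirror_right=True`` the right half is flipped along the left-right axis
before filtering, putting both orbits in a common anatomical frame (off by
default).
"""

from __future__ import annotations

import numpy as np

from .layers import Layer, Param, xavier_uniform

STAGES = ("stage1", "stage2", "stage3", "proposed")


def _split_halves(feat: np.ndarray, mode: str, mirror_right: bool):
    """(B, C, H, W) -> (left_half, right_half), each (B, n, Hh, Wh)."""
    if mode == "spatial":
        w = feat.shape[3]
        if w % 2:
            raise ValueError(f"cannot split odd width {w} into orbits")
        right, left = feat[..., : w // 2], feat[..., w // 2 :]
        if mirror_right:
            right = right[..., ::-1]
    elif mode == "channel":
        c = feat.shape[1]
        if c % 2:
            raise ValueError(f"cannot split odd channel count {c} into orbits")
        right, left = feat[:, : c // 2], feat[:, c // 2 :]
        if mirror_right:
            right = right[:, ::-1]
    else:
        raise ValueError(f"unknown split mode {mode!r}")
    return left, right


def _merge_halves(dleft: np.ndarray, dright: np.ndarray, mode: str,
                  mirror_right: bool) -> np.ndarray:
    if mirror_right:
        dright = dright[..., ::-1] if mode == "spatial" else dright[:, ::-1]
    axis = 3 if mode == "spatial" else 1
    return np.concatenate([dright, dleft], axis=axis)


def half_depthwise_forward(
    feat: np.ndarray,
    weights_left: np.ndarray,
    weights_right: np.ndarray,
    lr_axis: str,
    bias_left: np.ndarray | None = None,
    bias_right: np.ndarray | None = None,
    mirror_right: bool = False,
) -> np.ndarray:
    """Pure half-depthwise comparison of one feature map -> (n, 2) values.

    ``feat`` is (C, H, W); ``lr_axis`` is ``"width"`` (axial/coronal: split
    the in-plane width) or ``"slice"`` (sagittal: split the channel axis).
    Per side, filter ``c`` has the full spatial extent of its half and
    produces one scalar by valid correlation plus bias.  Column 0 of the
    output is the patient-left block, column 1 the patient-right block.
    """
    mode = {"width": "spatial", "slice": "channel"}[lr_axis]
    left, right = _split_halves(feat[None], mode, mirror_right)
    out = []
    for half, w, b in ((left, weights_left, bias_left),
                       (right, weights_right, bias_right)):
        vals = np.einsum("bchw,chw->bc", half, w)[0]
        if b is not None:
            vals = vals + b
        out.append(vals)
    return np.stack(out, axis=1)


class HalfComparison(Layer):
    """Layer-3 comparison over pre-split orbit halves, all ablation stages.

    ``mode`` is ``"spatial"`` or ``"channel"``; ``channels`` is the channel
    count of the incoming map; the per-side filter/channel count is
    ``channels`` for spatial maps and ``channels // 2`` for channel maps.
    Output is (B, 2*n): patient-left block first, then patient-right.
    """

    def __init__(self, mode: str, channels: int, half_hw: tuple[int, int],
                 stage: str, rng: np.random.Generator, mirror_right: bool = False):
        if stage not in STAGES:
            raise ValueError(f"unknown stage {stage!r}; expected one of {STAGES}")
        self.mode, self.stage, self.mirror_right = mode, stage, mirror_right
        self.half_hw = tuple(half_hw)
        self.n = channels if mode == "spatial" else channels // 2
        hh, hw = self.half_hw
        fan = self.n * hh * hw if stage == "stage1" else hh * hw

        if stage == "stage1":
            # channel-mixing filters of full-half extent, shared across sides
            self.w_left = Param(xavier_uniform(rng, (self.n, self.n, hh, hw), fan, self.n))
            self.b_left = Param(np.zeros(self.n, dtype=np.float32))
            self.w_right, self.b_right = self.w_left, self.b_left
        else:
            tied = stage == "stage3" or (stage == "stage2" and mode == "spatial")
            self.w_left = Param(xavier_uniform(rng, (self.n, hh, hw), fan, 1))
            self.b_left = Param(np.zeros(self.n, dtype=np.float32))
            if tied:
                self.w_right, self.b_right = self.w_left, self.b_left
            else:
                self.w_right = Param(xavier_uniform(rng, (self.n, hh, hw), fan, 1))
                self.b_right = Param(np.zeros(self.n, dtype=np.float32))

    @property
    def tied(self) -> bool:
        return self.w_right is self.w_left

    def params(self):
        base = [self.w_left, self.b_left]
        if not self.tied:
            base += [self.w_right, self.b_right]
        return base

    def _apply(self, half: np.ndarray, w: Param, b: Param) -> np.ndarray:
        if self.stage == "stage1":
            return np.einsum("bchw,fchw->bf", half, w.value, optimize=True) + b.value
        return np.einsum("bchw,chw->bc", half, w.value, optimize=True) + b.value

    def forward(self, feat: np.ndarray) -> np.ndarray:
        left, right = _split_halves(feat, self.mode, self.mirror_right)
        self._halves = (left, right)
        self._in_shape = feat.shape
        out_l = self._apply(left, self.w_left, self.b_left)
        out_r = self._apply(right, self.w_right, self.b_right)
        return np.concatenate([out_l, out_r], axis=1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        left, right = self._halves
        dl, dr = dout[:, : self.n], dout[:, self.n :]
        dhalves = []
        for half, d, w, b in ((left, dl, self.w_left, self.b_left),
                              (right, dr, self.w_right, self.b_right)):
            if self.stage == "stage1":
                w.grad += np.einsum("bchw,bf->fchw", half, d, optimize=True)
                dhalf = np.einsum("bf,fchw->bchw", d, w.value, optimize=True)
            else:
                w.grad += np.einsum("bchw,bc->chw", half, d, optimize=True)
                dhalf = d[:, :, None, None] * w.value[None]
            b.grad += d.sum(axis=0)
            dhalves.append(dhalf)
        self._halves = None
        return _merge_halves(dhalves[0], dhalves[1], self.mode, self.mirror_right)
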