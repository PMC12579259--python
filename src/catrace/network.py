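"""Multimodal encoder-FPN-decoder model for per-voxel backbone, Calpha and
amino-acid classification.

Architecture (channel counts at ``width_scale=1``):

* density path: four parallel 3D convolutions with kernel sizes 3/5/7/9
  whose outputs concatenate to 128 channels, followed by a channel
  self-attention block (average pooling + 1x1 conv stack, output multiplied
  onto the concatenated features);
* prior path: a 3x3x3 feature convolution taking the 24-channel structure
  encoding to 64 channels, scaled by a feature gate; when no prior is
  supplied, a zero-filled encoding is substituted so the density-only path
  is always available;
* fusion to a 64-channel joint representation (with light dropout);
* three encoder blocks of 128/256/512 filters, each a channel-lifting
  convolution (stride 2 by default, giving a 3-level pyramid), a residual
  block of three 3x3x3 convolutions, squeeze-and-excitation, dual
  local/global attention, and a transition convolution;
* an FPN with 1x1 lateral convolutions to a uniform 64-channel
  representation, top-down trilinear upsampling with one smoothing
  convolution per level, softmax-normalized learnable per-scale weights,
  and concatenation to 192 channels at full resolution;
* cascading decoders: a 4-channel backbone head, a 4-channel Calpha head
  fed the FPN features plus the backbone logits, and a 21-channel
  amino-acid head fed the FPN features plus both upstream logits.

``width_scale`` divides every width for desk-scale CPU use.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn
from .nn import tensor as T
from .nn.tensor import Tensor
from .constants import N_AA, N_ENCODE_CHANNELS, PATCH_SIZE
from .map_io import DensityMap, partition_map, stitch_volumes
from .struct_codec import EncodedVolume


class ConfigError(ValueError):
    pass


@dataclass
class ModelConfig:
    base_channels: int = 64
    encoder_channels: tuple[int, int, int] = (128, 256, 512)
    fpn_lateral: int = 64
    width_scale: int = 1
    dropout: float = 0.01
    downsample: bool = True          # stride-2 per encoder (3-level pyramid)
    ms_kernels: tuple[int, ...] = (3, 5, 7, 9)

    def __post_init__(self) -> None:
        if self.width_scale < 1:
            raise ConfigError("width_scale must be >= 1")
        if any(b <= a for a, b in zip(self.encoder_channels, self.encoder_channels[1:])):
            raise ConfigError("encoder_channels must be strictly increasing")
        if min(self.base_channels, self.fpn_lateral, *self.encoder_channels) < 1:
            raise ConfigError("all widths must be >= 1")

    def scaled(self, n: int) -> int:
        return max(1, n // self.width_scale)


@dataclass
class PredictionVolumes:
    """Per-voxel class probabilities aligned to a density map."""

    backbone_p: np.ndarray          # (nz, ny, nx), P(backbone-atom class)
    calpha_p: np.ndarray            # (nz, ny, nx), P(Calpha class)
    amino_p: np.ndarray             # (20, nz, ny, nx), sums to 1 per voxel

    def __post_init__(self) -> None:
        if self.amino_p.shape[0] != N_AA:
            raise ValueError(f"amino_p must have {N_AA} channels")
        if self.backbone_p.shape != self.calpha_p.shape != self.amino_p.shape[1:]:
            raise ValueError("prediction volumes must share one map shape")


class _Encoder(nn.Module):
    def __init__(self, cin: int, width: int, rng, stride: int):
        super().__init__()
        self.lift = nn.ConvBlock(cin, width, 3, rng, stride=stride)
        self.res = [nn.ConvBlock(width, width, 3, rng) for _ in range(3)]
        self.se = nn.ChannelGate(width, 8, rng)
        self.local_attn = nn.SpatialGate(width, rng)
        self.global_attn = nn.ChannelGate(width, 4, rng)
        self.transition = nn.ConvBlock(2 * width, width, 3, rng)

    def __call__(self, x: Tensor) -> Tensor:
        x = self.lift(x)
        h = x
        for blk in self.res:
            h = blk(h)
        h = self.se(T.add(x, h))
        local = self.local_attn(h)
        glob = self.global_attn(h)
        return self.transition(T.concat([local, glob]))


class FusionSegNet(nn.Module):
    """The full multimodal multi-task segmentation network."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        c = config.scaled
        self.config = config
        n_branch = len(config.ms_kernels)
        ms_width = c(128) // n_branch
        if ms_width < 1:
            raise ConfigError("width_scale too large for the multi-scale block")
        self.ms_concat_channels = ms_width * n_branch
        self.ms_convs = [nn.ConvBlock(1, ms_width, k, rng) for k in config.ms_kernels]
        self.density_attn = nn.ChannelGate(self.ms_concat_channels, 4, rng)
        self.prior_conv = nn.ConvBlock(N_ENCODE_CHANNELS, c(config.base_channels), 3, rng)
        self.prior_gate = nn.ChannelGate(c(config.base_channels), 4, rng)
        fused_in = self.ms_concat_channels + c(config.base_channels)
        self.fusion = nn.ConvBlock(fused_in, c(config.base_channels), 1, rng)
        widths = [c(e) for e in config.encoder_channels]
        stride = 2 if config.downsample else 1
        self.encoders = [
            _Encoder(cin, w, rng, stride)
            for cin, w in zip([c(config.base_channels)] + widths[:-1], widths)
        ]
        lat = c(config.fpn_lateral)
        self.fpn_channels = 3 * lat
        self.laterals = [nn.Conv3d(w, lat, 1, rng) for w in widths]
        self.smooths = [nn.ConvBlock(lat, lat, 3, rng) for _ in widths]
        self.scale_weights = Tensor(np.zeros(3), requires_grad=True)
        self.head_backbone = _Head(self.fpn_channels, c(config.base_channels), 4, rng)
        self.head_calpha = _Head(self.fpn_channels + 4, c(config.base_channels), 4, rng)
        self.head_amino = _Head(self.fpn_channels + 8, c(config.base_channels), N_AA + 1, rng)
        self._dropout_rng = np.random.default_rng(seed + 1)

    # -- forward -----------------------------------------------------------
    def __call__(self, density, prior=None):
        """Run the network on one patch.

        ``density``: (1, D, H, W) array or Tensor; ``prior``: (24, D, H, W)
        or None (absent prior substitutes a zero-filled encoding).  Returns
        ``(backbone_logits, calpha_logits, amino_logits)`` Tensors of
        channel counts 4/4/21 at the input's spatial shape.
        """
        x = density if isinstance(density, Tensor) else Tensor(density)
        if x.data.ndim != 4 or x.data.shape[0] != 1:
            raise ValueError(f"density patch must be (1, D, H, W), got {x.data.shape}")
        spatial = x.data.shape[1:]
        if prior is None:
            prior_arr = np.zeros((N_ENCODE_CHANNELS,) + spatial, dtype=np.float32)
            p = Tensor(prior_arr)
        else:
            p = prior if isinstance(prior, Tensor) else Tensor(np.asarray(prior, dtype=np.float32))
            if p.data.shape != (N_ENCODE_CHANNELS,) + spatial:
                raise ValueError(
                    f"prior patch shape {p.data.shape} does not match density {x.data.shape}")

        ms = T.concat([blk(x) for blk in self.ms_convs])
        density_feats = self.density_attn(ms)
        prior_feats = self.prior_gate(self.prior_conv(p))
        fused = self.fusion(T.concat([density_feats, prior_feats]))
        fused = T.dropout(fused, self.config.dropout, self._dropout_rng, self.training)

        enc_outs = []
        h = fused
        for enc in self.encoders:
            h = enc(h)
            enc_outs.append(h)

        # FPN: lateral -> top-down merge -> per-level smoothing
        lats = [lat(e) for lat, e in zip(self.laterals, enc_outs)]
        merged = [None, None, lats[2]]
        merged[1] = T.add(lats[1], T.upsample_trilinear(merged[2], lats[1].data.shape[1:]))
        merged[0] = T.add(lats[0], T.upsample_trilinear(merged[1], lats[0].data.shape[1:]))
        pyramid = []
        for lvl, smooth in zip(merged, self.smooths):
            s = smooth(lvl)
            up = T.upsample_trilinear(s, spatial) if s.data.shape[1:] != spatial else s
            pyramid.append(up)
        weighted = [T.mul(p_, T.softmax_weight(self.scale_weights, i))
                    for i, p_ in enumerate(pyramid)]
        fpn = T.concat(weighted)

        bb = self.head_backbone(fpn)
        ca = self.head_calpha(T.concat([fpn, bb]))
        aa = self.head_amino(T.concat([fpn, bb, ca]))
        return bb, ca, aa

    @property
    def fpn_scale_softmax(self) -> np.ndarray:
        e = np.exp(self.scale_weights.data - self.scale_weights.data.max())
        return e / e.sum()


class _Head(nn.Module):
    """Task decoder: two 1x1x1 convolutions with progressive channel reduction."""

    def __init__(self, cin: int, hidden: int, cout: int, rng):
        super().__init__()
        self.reduce = nn.ConvBlock(cin, hidden, 1, rng)
        self.out = nn.Conv3d(hidden, cout, 1, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.out(self.reduce(x))


def build_model(config: ModelConfig, seed: int = 0) -> FusionSegNet:
    """Construct a seeded model instance."""
    return FusionSegNet(config, seed=seed)


def _softmax(x: np.ndarray, axis: int = 0) -> np.ndarray:
    m = x.max(axis=axis, keepdims=True)
    e = np.exp(x - m)
    return e / e.sum(axis=axis, keepdims=True)


def logits_to_probabilities(bb_logits, ca_logits, aa_logits):
    """Convert head logits to the named class probabilities.

    The background and neighbour channels of the backbone/Calpha heads are
    removed and a softmax over the remaining {other-atom, target-atom}
    channels yields the target-class probability; the no-amino channel of
    the amino head is removed and a softmax over the 20 types yields the
    amino-acid probability vector.
    """
    bb = np.asarray(bb_logits.data if isinstance(bb_logits, Tensor) else bb_logits)
    ca = np.asarray(ca_logits.data if isinstance(ca_logits, Tensor) else ca_logits)
    aa = np.asarray(aa_logits.data if isinstance(aa_logits, Tensor) else aa_logits)
    backbone_p = _softmax(bb[2:4])[1]
    calpha_p = _softmax(ca[2:4])[1]
    amino_p = _softmax(aa[1:])
    return backbone_p, calpha_p, amino_p


def predict_full_map(model: FusionSegNet, dmap: DensityMap,
                     prior: EncodedVolume | None = None) -> PredictionVolumes:
    """Partition a normalized map (and optional prior encoding), run the
    model patch-by-patch, and stitch the probability cores back to the
    map's shape."""
    was_training = model.training
    model.eval()
    try:
        d_patches = partition_map(dmap)
        if prior is not None:
            if prior.data.shape[1:] != dmap.shape:
                raise ValueError(
                    f"prior shape {prior.data.shape[1:]} does not match map {dmap.shape}")
            p_patches = partition_map(prior.data.astype(np.float32))
        else:
            p_patches = [None] * len(d_patches)
        from .map_io import GridPatch
        out_patches = []
        for dp, pp in zip(d_patches, p_patches):
            bb, ca, aa = model(dp.data[None], None if pp is None else pp.data)
            backbone_p, calpha_p, amino_p = logits_to_probabilities(bb, ca, aa)
            stackv = np.concatenate([backbone_p[None], calpha_p[None], amino_p])
            out_patches.append(GridPatch(stackv, dp.core_offset))
        stacked = stitch_volumes(out_patches, dmap.shape)
    finally:
        model.train(was_training)
    return PredictionVolumes(backbone_p=stacked[0], calpha_p=stacked[1],
                             amino_p=stacked[2:])


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: FusionSegNet, path, extra: dict | None = None) -> None:
    """Write weights + config (+ channel-order manifest) to an .npz file."""
    from .constants import AA_ORDER, BACKBONE_ATOMS

    meta = {
        "config": asdict(model.config),
        "channel_order": {"backbone_atoms": list(BACKBONE_ATOMS),
                          "amino_acids": list(AA_ORDER)},
        "extra": extra or {},
    }
    state = {f"param/{k}": v for k, v in model.state_dict().items()}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **state)


def load_checkpoint(path) -> tuple[FusionSegNet, dict]:
    """Rebuild a model from a checkpoint; returns (model, metadata)."""
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        cfg_dict = dict(meta["config"])
        cfg_dict["encoder_channels"] = tuple(cfg_dict["encoder_channels"])
        cfg_dict["ms_kernels"] = tuple(cfg_dict["ms_kernels"])
        config = ModelConfig(**cfg_dict)
        model = build_model(config, seed=0)
        state = {k[len("param/"):]: z[k] for k in z.files if k.startswith("param/")}
    model.load_state_dict(state)
    model.eval()
    return model, meta
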