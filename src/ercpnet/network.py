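"""Network assembly: stem + CER(+attention) stages + fusion head.

Four variants are exposed:

* ``er_net``        — stem + three CER blocks + classification head.
* ``er_net_cbam``   — each CER stage followed by a CBAM attention block.
* ``erc_net``       — each CER stage followed by an adaptive (ACA) block.
* ``ercp_net``      — erc_net plus bidirectional fusion of the last two
                      stage outputs before the head (the default).

With the default stem width 16 and three stages, channels progress
16 -> 48 -> 144 -> 432, the fusion block emits 1296, and a 416x416 input
reaches the head at 13x13.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .attention import ACABlock, CBAMBlock, IGPDFParams
from .autodiff import Module, Tensor
from .blocks import BIFBlock, BIFConfig, CERBlock, CERConfig, Stem
from .layers import Linear

__all__ = ["NetworkConfig", "LayerSummary", "Network", "build_network",
           "save_checkpoint", "load_checkpoint"]

VARIANTS = ("er_net", "er_net_cbam", "erc_net", "ercp_net")

CHECKPOINT_FORMAT_VERSION = 1


@dataclass(frozen=True)
class NetworkConfig:
    variant: str = "ercp_net"
    stem_width: int = 16
    num_stages: int = 3
    num_classes: int = 38
    input_size: int = 416
    igpdf_mu: float = 0.0
    igpdf_sigma: float = 1.0
    igpdf_channel_normalizer: float = 2048.0
    attention_combination: str = "multiplicative"
    bif_out_channels: int | None = None
    bif_upsample_mode: str = "nearest"
    cbam_reduction_ratio: int = 16
    seed: int = 0

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; expected one of {VARIANTS}")
        if self.num_classes < 2:
            raise ValueError("num_classes must be >= 2")
        if self.input_size % (2 ** (self.num_stages + 2)) != 0:
            raise ValueError(
                f"input_size {self.input_size} must be divisible by "
                f"2^(num_stages+2) = {2 ** (self.num_stages + 2)}")

    @property
    def igpdf(self) -> IGPDFParams:
        return IGPDFParams(self.igpdf_mu, self.igpdf_sigma, self.igpdf_channel_normalizer)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        return cls(**d)


@dataclass
class LayerSummary:
    """Ordered (layer name, output shape) records from a tracing forward pass."""

    entries: list

    def as_dict(self) -> dict:
        return dict(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def format_table(self) -> str:
        width = max(len(n) for n, _ in self.entries) + 2
        lines = [f"{'Layer':<{width}}Tensor size"]
        for name, shape in self.entries:
            lines.append(f"{name:<{width}}[{','.join(str(s) for s in shape)}]")
        return "\n".join(lines)


class Network(Module):
    def __init__(self, config: NetworkConfig):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.stem = Stem(config.stem_width, rng=rng)
        self.cer_blocks: list[CERBlock] = []
        self.attn_blocks: list[Module] = []
        c = config.stem_width
        for i in range(config.num_stages):
            cer = CERBlock(CERConfig(in_channels=c), rng=rng)
            setattr(self, f"cer_{i + 1}", cer)
            self.cer_blocks.append(cer)
            c *= 3
            if config.variant == "er_net_cbam":
                att = CBAMBlock(c, config.cbam_reduction_ratio, rng=rng)
            elif config.variant in ("erc_net", "ercp_net"):
                att = ACABlock(c, config.igpdf, config.attention_combination, rng=rng)
            else:
                att = None
            if att is not None:
                setattr(self, f"attn_{i + 1}", att)
            self.attn_blocks.append(att)
        self.stage_channels = [config.stem_width * 3 ** (k + 1)
                               for k in range(config.num_stages)]
        if config.variant == "ercp_net":
            bif_cfg = BIFConfig(mid_channels=self.stage_channels[-2],
                                deep_channels=self.stage_channels[-1],
                                out_channels=config.bif_out_channels,
                                upsample_mode=config.bif_upsample_mode)
            self.bif = BIFBlock(bif_cfg, rng=rng)
            head_channels = bif_cfg.resolved_out_channels
        else:
            self.bif = None
            head_channels = self.stage_channels[-1]
        self.head_channels = head_channels
        self.fc = Linear(head_channels, config.num_classes, rng=rng)

    @property
    def num_classes(self) -> int:
        return self.config.num_classes

    # ------------------------------------------------------------------ #
    def _check_input(self, x: Tensor) -> None:
        expect = (3, self.config.input_size, self.config.input_size)
        if tuple(x.shape[1:]) != expect:
            raise ValueError(f"expected input shape (N, {expect[0]}, {expect[1]}, "
                             f"{expect[2]}), received (N, {x.shape[1]}, {x.shape[2]}, "
                             f"{x.shape[3]})")

    def forward_features(self, x: Tensor, record: dict | None = None) -> Tensor:
        """Run the convolutional trunk; optionally record named activations."""
        self._check_input(x)

        def rec(name, t):
            if record is not None:
                record[name] = t

        rec("input", x)
        h = self.stem.conv_forward(x)
        rec("stem_conv", h)
        h = h.maxpool2d(3, stride=2, padding=1)
        rec("stem_pool", h)
        stage_outputs = []
        for i, (cer, att) in enumerate(zip(self.cer_blocks, self.attn_blocks), start=1):
            h = cer(h)
            rec(f"cer_{i}", h)
            if att is not None:
                h = att(h)
                rec(f"attn_{i}", h)
            stage_outputs.append(h)
        if self.bif is not None:
            h = self.bif(stage_outputs[-2], stage_outputs[-1])
            rec("bif", h)
        return h

    def forward_logits(self, x: Tensor, record: dict | None = None) -> Tensor:
        h = self.forward_features(x, record=record)
        pooled = h.mean(axis=(2, 3))
        if record is not None:
            record["gap"] = pooled
        logits = self.fc(pooled)
        if record is not None:
            record["fc"] = logits
        return logits

    def forward(self, x: Tensor) -> np.ndarray:
        """Class probabilities, one row per sample (softmax over logits)."""
        logits = self.forward_logits(x).data
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    __call__ = forward

    # ------------------------------------------------------------------ #
    def layer_names(self) -> list:
        """Names usable as class-activation-map targets."""
        record: dict = {}
        s = self.config.input_size
        was_training = self.training
        self.eval()
        self.forward_logits(Tensor(np.zeros((1, 3, s, s))), record=record)
        if was_training:
            self.train()
        return [k for k in record if k not in ("input", "gap", "fc")]

    def shape_summary(self, input_shape: tuple | None = None) -> LayerSummary:
        """Trace one forward pass and report each named layer's output shape."""
        s = self.config.input_size
        shape = input_shape or (3, s, s)
        record: dict = {}
        was_training = self.training
        self.eval()
        probs_shape = self.forward_logits(Tensor(np.zeros((1,) + tuple(shape))),
                                          record=record).shape
        if was_training:
            self.train()
        display = {"input": "Input", "stem_conv": "Conv", "stem_pool": "MaxPool",
                   "bif": "BIF-Block", "gap": "Global average pool",
                   "fc": "Fully connected layer"}
        attn_label = {"er_net_cbam": "CBAM", "erc_net": "ACA-Block",
                      "ercp_net": "ACA-Block"}.get(self.config.variant, "")
        entries = []
        for name, t in record.items():
            if name.startswith("cer_"):
                label = f"CER-Block_{name.split('_')[1]}"
            elif name.startswith("attn_"):
                label = f"{attn_label}_{name.split('_')[1]}"
            else:
                label = display[name]
            shp = tuple(int(v) for v in t.shape[1:])
            if name == "gap":
                shp = shp + (1, 1)
            entries.append((label, shp))
        entries.append(("Softmax", tuple(int(v) for v in probs_shape[1:])))
        return LayerSummary(entries)

    def count_parameters(self) -> tuple:
        """(total learnable scalars, per-named-layer counts)."""
        per_layer: dict = {}
        for name, p in self.named_parameters():
            top = name.split(".")[0]
            per_layer[top] = per_layer.get(top, 0) + int(p.data.size)
        return sum(per_layer.values()), per_layer


def build_network(config: NetworkConfig) -> Network:
    """Build a variant network with seed-deterministic initialization."""
    return Network(config)


# ---------------------------------------------------------------------- #
#  Checkpoints: versioned and self-describing (the config travels along)
# ---------------------------------------------------------------------- #
def save_checkpoint(net: Network, path: str, extra: dict | None = None) -> None:
    meta = {"format_version": CHECKPOINT_FORMAT_VERSION,
            "config": net.config.to_dict(), "extra": extra or {}}
    arrays = {k.replace(":", "__"): v for k, v in net.state_dict().items()}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(path: str) -> Network:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"].tobytes()).decode())
        if meta["format_version"] > CHECKPOINT_FORMAT_VERSION:
            raise ValueError(f"checkpoint format {meta['format_version']} is newer "
                             f"than supported ({CHECKPOINT_FORMAT_VERSION})")
        net = build_network(NetworkConfig.from_dict(meta["config"]))
        state = {k.replace("__", ":", 1): data[k] for k in data.files if k != "__meta__"}
        net.load_state_dict(state)
    return net
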