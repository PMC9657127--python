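"""Classifier backbones and activation surgery.

Two families are provided: SE-ResNet-50 (ResNet-50 bottlenecks with
squeeze-and-excitation channel gating, reduction 16) and the
depthwise-separable MobileNet (v1, width 1.0). A :class:`ReplacementPlan`
says which of the four stages (and optionally the stem) swap their scalar
ReLUs for CroReLU activations with a given cross window.

The surgery replaces each activation *in place* — same site, same channel
count — leaving every convolution and normalisation untouched, so the
parameter delta between any two plans is exactly the summed condition
parameters of the sites that differ. Read across unit boundaries, a
replaced region executes as normalisation -> CroReLU -> convolution
("pre-cross-activation"); unreplaced regions keep the familiar
convolution -> normalisation -> ReLU ordering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .core import CroReLU, condition_param_count
from .nn.module import Module, Sequential

__all__ = [
    "BackboneSpec",
    "ReplacementPlan",
    "SEModuleSpec",
    "SEBlock",
    "se_block",
    "build_backbone",
    "build_toy_cnn",
    "count_parameters",
    "activation_sites",
    "plan_extra_params",
]

FAMILIES = ("se_resnet50", "mobilenet")

# SE-ResNet-50 stage layout: (blocks, mid_channels, out_channels, first stride)
_RESNET50_STAGES = ((3, 64, 256, 1), (4, 128, 512, 2), (6, 256, 1024, 2), (3, 512, 2048, 2))

# MobileNet v1 separable blocks: (in_channels, out_channels, stride),
# partitioned into four stages at the stride-2 boundaries.
_MOBILENET_BLOCKS = (
    ((32, 64, 1), (64, 128, 2)),
    ((128, 128, 1), (128, 256, 2)),
    ((256, 256, 1), (256, 512, 2)),
    ((512, 512, 1), (512, 512, 1), (512, 512, 1), (512, 512, 1), (512, 512, 1),
     (512, 1024, 2), (1024, 1024, 1)),
)


@dataclass(frozen=True)
class BackboneSpec:
    family: str = "se_resnet50"
    num_classes: int = 3
    se_reduction: int = 16
    input_size: tuple[int, int] = (224, 224)

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; choose from {FAMILIES}")
        if self.num_classes < 2:
            raise ValueError("num_classes must be >= 2")
        if self.family == "se_resnet50" and _RESNET50_STAGES[-1][2] % self.se_reduction:
            raise ValueError("se_reduction must divide the widest channel count")


@dataclass(frozen=True)
class ReplacementPlan:
    """Which activation sites become CroReLU."""

    window: tuple[int, int] | None = None
    stages_replaced: frozenset = frozenset()
    replace_stem: bool = False
    replace_se_internal: bool = False

    def __post_init__(self):
        stages = frozenset(self.stages_replaced)
        object.__setattr__(self, "stages_replaced", stages)
        if not stages.issubset({1, 2, 3, 4}):
            raise ValueError(f"stages_replaced must be a subset of {{1,2,3,4}}; got {set(stages)}")
        if (stages or self.replace_stem or self.replace_se_internal) and self.window is None:
            raise ValueError("a replacement plan with replaced sites needs a window")
        if self.window is not None:
            kh, kw = self.window
            if kh < 1 or kh % 2 == 0 or kw < 1 or kw % 2 == 0:
                raise ValueError(f"window extents must be odd and >= 1; got {self.window}")

    @property
    def is_baseline(self) -> bool:
        return not (self.stages_replaced or self.replace_stem or self.replace_se_internal)

    @classmethod
    def baseline(cls) -> "ReplacementPlan":
        return cls()

    @classmethod
    def full(cls, window: tuple[int, int] = (3, 3)) -> "ReplacementPlan":
        """Every backbone activation replaced (stem + all four stages)."""
        return cls(window=window, stages_replaced=frozenset({1, 2, 3, 4}), replace_stem=True)

    @classmethod
    def first_stages(cls, n: int, window: tuple[int, int] = (3, 3)) -> "ReplacementPlan":
        """The blockwise sweep: stages 1..n replaced, stem counted with stage 1."""
        if not 0 <= n <= 4:
            raise ValueError("n must be in 0..4")
        return cls(window=window if n else None,
                   stages_replaced=frozenset(range(1, n + 1)), replace_stem=n >= 1)


@dataclass
class SEModuleSpec:
    """Weights of one squeeze-and-excitation gate: squeeze (global average)
    -> reduce -> ReLU -> expand -> sigmoid -> per-channel rescale."""

    channels: int
    reduction: int = 16
    w_reduce: np.ndarray | None = None  # (channels//reduction, channels)
    b_reduce: np.ndarray | None = None
    w_expand: np.ndarray | None = None  # (channels, channels//reduction)
    b_expand: np.ndarray | None = None

    def __post_init__(self):
        if self.channels % self.reduction:
            raise ValueError("reduction must divide channels")
        hidden = self.channels // self.reduction
        if self.w_reduce is None:
            self.w_reduce = np.zeros((hidden, self.channels))
        if self.b_reduce is None:
            self.b_reduce = np.zeros(hidden)
        if self.w_expand is None:
            self.w_expand = np.zeros((self.channels, hidden))
        if self.b_expand is None:
            self.b_expand = np.zeros(self.channels)
        if np.shape(self.w_reduce) != (hidden, self.channels) or np.shape(self.w_expand) != (self.channels, hidden):
            raise ValueError("SE weight shapes inconsistent with channels/reduction")


def se_block(x: np.ndarray, spec: SEModuleSpec) -> np.ndarray:
    """Functional squeeze-and-excitation rescale of a 4-D activation array."""
    x = np.asarray(x)
    if x.ndim != 4 or x.shape[1] != spec.channels:
        raise ValueError(f"expected (N, {spec.channels}, H, W) input; got shape {x.shape}")
    s = x.mean(axis=(2, 3))
    z = np.maximum(s @ np.asarray(spec.w_reduce).T + spec.b_reduce, 0)
    gate = 1.0 / (1.0 + np.exp(-(z @ np.asarray(spec.w_expand).T + spec.b_expand)))
    return x * gate[:, :, None, None]


class _VectorActivation(Module):
    """Adapter applying a 4-D activation to (N, F) vectors as (N, F, 1, 1);
    used only when the SE-internal activation is ablated to CroReLU."""

    def __init__(self, act: Module):
        super().__init__()
        self.act = act

    def forward(self, x):
        return self.act(x[:, :, None, None])[:, :, 0, 0]

    def backward(self, grad_out):
        return self.act.backward(grad_out[:, :, None, None])[:, :, 0, 0]


class SEBlock(Module):
    """Squeeze-and-excitation channel gate, as a layer."""

    def __init__(self, channels: int, reduction: int = 16, rng: np.random.Generator | None = None,
                 internal_act: Module | None = None):
        super().__init__()
        if channels % reduction:
            raise ValueError("reduction must divide channels")
        hidden = channels // reduction
        self.gate = Sequential(
            nn.Linear(channels, hidden, rng=rng),
            internal_act or nn.ReLU(),
            nn.Linear(hidden, channels, rng=rng),
            nn.Sigmoid(),
        )
        self._cache = None

    def forward(self, x):
        s = x.mean(axis=(2, 3))
        g = self.gate(s)
        self._cache = (x, g)
        return x * g[:, :, None, None]

    def backward(self, grad_out):
        x, g = self._cache
        h, w = x.shape[2], x.shape[3]
        grad_x = grad_out * g[:, :, None, None]
        grad_g = (grad_out * x).sum(axis=(2, 3))
        grad_s = self.gate.backward(grad_g)
        grad_x = grad_x + grad_s[:, :, None, None] / (h * w)
        return grad_x


class SEBottleneck(Module):
    """1x1 -> 3x3 -> 1x1 bottleneck with SE gating and a residual skip."""

    def __init__(self, cin, mid, cout, stride, reduction, act_factory, rng):
        super().__init__()
        self.main = Sequential(
            nn.Conv2d(cin, mid, 1, rng=rng), nn.BatchNorm2d(mid), act_factory(mid),
            nn.Conv2d(mid, mid, 3, stride=stride, padding=1, rng=rng), nn.BatchNorm2d(mid), act_factory(mid),
            nn.Conv2d(mid, cout, 1, rng=rng), nn.BatchNorm2d(cout),
            SEBlock(cout, reduction, rng=rng),
        )
        if stride != 1 or cin != cout:
            self.shortcut = Sequential(nn.Conv2d(cin, cout, 1, stride=stride, rng=rng), nn.BatchNorm2d(cout))
        else:
            self.shortcut = None
        self.act_out = act_factory(cout)

    def forward(self, x):
        y = self.main(x)
        s = self.shortcut(x) if self.shortcut is not None else x
        return self.act_out(y + s)

    def backward(self, grad_out):
        g = self.act_out.backward(grad_out)
        grad_x = self.main.backward(g)
        if self.shortcut is not None:
            grad_x = grad_x + self.shortcut.backward(g)
        else:
            grad_x = grad_x + g
        return grad_x


def _make_act_factory(plan: ReplacementPlan, stage: int | None, rng: np.random.Generator):
    """stage=None means the stem."""
    replaced = plan.replace_stem if stage is None else (stage in plan.stages_replaced)

    def factory(channels: int) -> Module:
        if replaced:
            kh, kw = plan.window
            return CroReLU(channels, kh, kw, rng=rng)
        return nn.ReLU()

    return factory


def build_backbone(spec: BackboneSpec, plan: ReplacementPlan | None = None, seed: int = 0) -> Sequential:
    """Construct a classifier network for the given family and plan.

    With an empty plan the result is the stock post-activation baseline;
    replaced stages carry CroReLU at every activation site of the same
    channel count. Weight initialisation is seeded and identical across
    plans for all shared (conv/BN/SE/head) parameters.
    """
    plan = plan or ReplacementPlan.baseline()
    rng = np.random.default_rng(seed)
    act_rng = np.random.default_rng(np.random.default_rng(seed + 1).integers(2**31))
    if spec.family == "se_resnet50":
        return _build_se_resnet50(spec, plan, rng, act_rng)
    return _build_mobilenet(spec, plan, rng, act_rng)


def _build_se_resnet50(spec, plan, rng, act_rng):
    layers = [
        nn.Conv2d(3, 64, 7, stride=2, padding=3, rng=rng),
        nn.BatchNorm2d(64),
        _make_act_factory(plan, None, act_rng)(64),
        nn.MaxPool2d(3, stride=2, padding=1),
    ]
    cin = 64
    for stage_idx, (blocks, mid, cout, stride) in enumerate(_RESNET50_STAGES, start=1):
        act_factory = _make_act_factory(plan, stage_idx, act_rng)
        for b in range(blocks):
            layers.append(SEBottleneck(cin, mid, cout, stride if b == 0 else 1,
                                       spec.se_reduction, act_factory, rng))
            cin = cout
    layers += [nn.GlobalAvgPool(), nn.Linear(cin, spec.num_classes, rng=rng)]
    net = Sequential(*layers)
    if plan.replace_se_internal:
        _replace_se_internal(net, plan, act_rng)
    return net


def _build_mobilenet(spec, plan, rng, act_rng):
    stem_act = _make_act_factory(plan, None, act_rng)
    layers = [nn.Conv2d(3, 32, 3, stride=2, padding=1, rng=rng), nn.BatchNorm2d(32), stem_act(32)]
    for stage_idx, stage_blocks in enumerate(_MOBILENET_BLOCKS, start=1):
        act_factory = _make_act_factory(plan, stage_idx, act_rng)
        for cin, cout, stride in stage_blocks:
            layers += [
                nn.Conv2d(cin, cin, 3, stride=stride, padding=1, groups=cin, rng=rng),
                nn.BatchNorm2d(cin), act_factory(cin),
                nn.Conv2d(cin, cout, 1, rng=rng), nn.BatchNorm2d(cout), act_factory(cout),
            ]
    layers += [nn.GlobalAvgPool(), nn.Linear(1024, spec.num_classes, rng=rng)]
    return Sequential(*layers)


def _replace_se_internal(net: Module, plan: ReplacementPlan, rng: np.random.Generator):
    kh, kw = plan.window
    for mod in net.modules():
        if isinstance(mod, SEBlock):
            hidden = mod.gate[0].weight.shape[0]
            mod.gate._modules["1"] = _VectorActivation(CroReLU(hidden, kh, kw, rng=rng))
            mod.gate.layers[1] = mod.gate._modules["1"]


def build_toy_cnn(num_classes: int = 3, stage_channels: tuple[int, ...] = (8, 16, 32, 64),
                  in_channels: int = 3, window: tuple[int, int] | None = None,
                  stages_replaced: set | None = None, seed: int = 0) -> Sequential:
    """A small plain CNN (one conv-BN-activation per stage, stride-2 from the
    second stage on) for desk-scale experiments. ``window=None`` gives the
    ReLU variant; otherwise the activations of ``stages_replaced`` (1-based;
    default all stages) are CroReLU with that window."""
    rng = np.random.default_rng(seed)
    act_rng = np.random.default_rng(np.random.default_rng(seed + 1).integers(2**31))
    if window is not None and stages_replaced is None:
        stages_replaced = set(range(1, len(stage_channels) + 1))

    def act(stage, channels):
        if window is not None and stage in stages_replaced:
            return CroReLU(channels, window[0], window[1], rng=act_rng)
        return nn.ReLU()

    layers = []
    cin = in_channels
    for i, c in enumerate(stage_channels):
        layers += [nn.Conv2d(cin, c, 3, stride=1 if i == 0 else 2, padding=1, rng=rng),
                   nn.BatchNorm2d(c), act(i + 1, c)]
        cin = c
    layers += [nn.GlobalAvgPool(), nn.Linear(cin, num_classes, rng=rng)]
    return Sequential(*layers)


def count_parameters(net: Module) -> int:
    """Total trainable scalar parameters of a built network."""
    return net.num_parameters()


def activation_sites(spec: BackboneSpec) -> dict:
    """Channel counts of every backbone activation site, keyed by 'stem' and
    stage number. Derived from the architecture tables, independently of any
    built network (tests cross-check it against module enumeration)."""
    if spec.family == "se_resnet50":
        sites = {"stem": [64]}
        for stage_idx, (blocks, mid, cout, _) in enumerate(_RESNET50_STAGES, start=1):
            sites[stage_idx] = [c for _ in range(blocks) for c in (mid, mid, cout)]
    else:
        sites = {"stem": [32]}
        for stage_idx, stage_blocks in enumerate(_MOBILENET_BLOCKS, start=1):
            sites[stage_idx] = [c for cin, cout, _ in stage_blocks for c in (cin, cout)]
    return sites


def plan_extra_params(spec: BackboneSpec, plan: ReplacementPlan) -> int:
    """Condition parameters a plan adds over the ReLU baseline (SE-internal
    sites excluded; they are vector-valued and ablated separately)."""
    if plan.is_baseline:
        return 0
    kh, kw = plan.window
    sites = activation_sites(spec)
    total = 0
    if plan.replace_stem:
        total += sum(condition_param_count(c, kh, kw) for c in sites["stem"])
    for stage in plan.stages_replaced:
        total += sum(condition_param_count(c, kh, kw) for c in sites[stage])
    return total
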