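"""FD-CNN: slice-wise prediction of nine per-beam dose distributions.

Input A is an 8-channel image (the query PTV slice with its six neighbors,
plus the OAR slice); a three-step strided-convolution encoder reduces
192x192 to 24x24 at 128 channels, a three-step transposed-convolution
decoder restores 192x192 at 72 channels, the nine beam-template slices are
concatenated, and a final convolution block emits the nine field-dose
slices.  Swish activations throughout, linear output.

The loss is a composite of per-beam field-dose error and total-dose error
(total = channel sum), both restricted to the ROI (PTV + 1 cm) and
normalized by the ROI pixel count, with the total-dose term weighted by
``mu``.  Internally the network works on doses as fractions of the
prescription (% Rx / 100).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .anatomy import FDSample, PhantomCase
from .dose_engine import FieldDoseSet
from . import nn
from .nn import swish  # re-exported: the network's activation

DOSE_SCALE = 0.01  # % Rx -> network units (fraction of prescription)


@dataclass(frozen=True)
class FDNetConfig:
    """Architecture and training settings for the field-dose network.

    Defaults target the clinical-scale 192x192 grid; ``coarse()`` is the
    reduced-width desk-scale preset.  ``n_adjacent`` controls how many PTV
    neighbor-slice pairs enter the input (3 = the full query +- 3 stack);
    ``use_templates=False`` removes the beam-template input (ablation).
    """

    image_size: int = 192
    n_adjacent: int = 3
    down_widths: tuple[int, ...] = (32, 64, 128)
    up_widths: tuple[int, ...] = (96, 84, 72)
    final_width: int = 96
    block_depth: int = 2       # convolutions per down/up block (strided + refine)
    head_kernel: int = 3       # kernel of the first output-block convolution
    template_channels: int = 9
    out_channels: int = 9
    activation: str = "swish"
    use_templates: bool = True
    mu: float = 1.0
    lr: float = 1e-3
    patience: int = 8
    val_fraction: float = 0.10
    batch_size: int = 16
    max_epochs: int = 200
    seed: int = 0

    @property
    def in_channels(self) -> int:
        return 2 * self.n_adjacent + 1 + 1  # PTV stack + OAR slice

    @staticmethod
    def coarse(**overrides) -> "FDNetConfig":
        cfg = FDNetConfig(
            image_size=48,
            down_widths=(16, 32, 48),
            up_widths=(32, 24, 16),
            final_width=24,
            block_depth=1,
            head_kernel=1,
            max_epochs=60,
        )
        return replace(cfg, **overrides)


# ---------------------------------------------------------------------------
# Loss (single-sample public form + batched training form)
# ---------------------------------------------------------------------------

def fd_loss(
    fd_pred: np.ndarray,
    fd_bench: np.ndarray,
    roi_mask: np.ndarray,
    mu: float = 1.0,
) -> float:
    """Composite field-dose + total-dose squared error over the ROI.

    ``fd_pred``/``fd_bench`` are (n_beams, ...) stacks; ``roi_mask`` is the
    binary ROI with the trailing shape.  Returns
    ``(sum_beam sum_ROI (FDb-FDp)^2 + mu * sum_ROI (TDb-TDp)^2) / N(ROI)``.
    """
    fd_pred = np.asarray(fd_pred, dtype=np.float64)
    fd_bench = np.asarray(fd_bench, dtype=np.float64)
    roi = np.asarray(roi_mask) > 0
    n_roi = int(roi.sum())
    if n_roi == 0:
        raise ValueError("empty ROI in fd_loss")
    if fd_pred.shape != fd_bench.shape:
        raise ValueError("prediction/target shape mismatch")
    diff = (fd_bench - fd_pred) * roi[None]
    fd_term = float(np.sum(diff**2))
    td_diff = (fd_bench.sum(axis=0) - fd_pred.sum(axis=0)) * roi
    td_term = mu * float(np.sum(td_diff**2))
    return (fd_term + td_term) / n_roi


def _fd_loss_batch(pred: np.ndarray, bench: np.ndarray, roi: np.ndarray, mu: float):
    """Mean per-sample composite loss over a batch, with gradient wrt pred.

    ``pred``/``bench``: (N, H, W, B); ``roi``: (N, H, W, 1) binary.
    """
    roi = roi.astype(pred.dtype)
    n_roi = roi.sum(axis=(1, 2, 3), keepdims=True)  # (N,1,1,1), nonzero by contract
    diff = (pred - bench) * roi
    td_diff = diff.sum(axis=3, keepdims=True)
    per_sample = (np.sum(diff**2, axis=(1, 2, 3), keepdims=True)
                  + mu * np.sum(td_diff**2, axis=(1, 2, 3), keepdims=True)) / n_roi
    n = pred.shape[0]
    val = float(per_sample.sum()) / n
    grad = (2.0 * diff + 2.0 * mu * td_diff * roi) / n_roi / n
    return val, grad


# ---------------------------------------------------------------------------
# Network
# ---------------------------------------------------------------------------

class FDNet:
    """Encoder-decoder with template concatenation before the output block."""

    def __init__(self, config: FDNetConfig):
        if config.image_size % 8 != 0:
            raise ValueError("image size must be divisible by 2^3")
        self.config = config
        rng = np.random.default_rng(config.seed)
        act = config.activation

        def block(layers):
            return nn.Sequential(*layers)

        down = []
        c = config.in_channels
        for width in config.down_widths:
            down += [
                nn.Conv2D(c, width, k=4, stride=2, rng=rng, pad=1),
                nn.make_activation(act),
            ]
            if config.block_depth > 1:
                down += [nn.Conv2D(width, width, k=3, stride=1, rng=rng),
                         nn.make_activation(act)]
            c = width
        up = []
        for width in config.up_widths:
            up += [nn.ConvTranspose2D(c, width, rng=rng), nn.make_activation(act)]
            if config.block_depth > 1:
                up += [nn.Conv2D(width, width, k=3, stride=1, rng=rng),
                       nn.make_activation(act)]
            c = width
        self.trunk = block(down + up)
        c_cat = c + config.template_channels
        self.head = block([
            nn.Conv2D(c_cat, config.final_width, k=config.head_kernel,
                      stride=1, rng=rng),
            nn.make_activation(act),
            nn.Conv2D(config.final_width, config.out_channels, k=3, stride=1, rng=rng),
        ])
        self._n_templates = config.template_channels

    def forward(self, masks: np.ndarray, templates: np.ndarray, train: bool = True):
        if not self.config.use_templates:
            templates = np.zeros_like(templates)
        h = self.trunk.forward(masks.astype(nn.DTYPE), train=train)
        cat = np.concatenate([h, templates.astype(nn.DTYPE)], axis=3)
        return self.head.forward(cat, train=train)

    def backward(self, grad):
        g = self.head.backward(grad)
        g_trunk = g[..., : -self._n_templates]
        return self.trunk.backward(np.ascontiguousarray(g_trunk))

    def params(self):
        return self.trunk.params() + self.head.params()

    @property
    def n_params(self) -> int:
        return nn.n_params(self)


def build_fd_cnn(config: FDNetConfig | None = None) -> FDNet:
    return FDNet(config or FDNetConfig())


# ---------------------------------------------------------------------------
# Training and inference
# ---------------------------------------------------------------------------

def samples_to_arrays(samples: list[FDSample], config: FDNetConfig):
    """Stack FDSamples into batched float32 channels-last training arrays
    (doses in network units, % Rx / 100)."""
    na = config.n_adjacent
    lo, hi = 3 - na, 4 + na
    masks = np.stack(
        [np.concatenate([s.ptv_stack[lo:hi], s.oar_slice[None]]) for s in samples]
    )
    masks = np.moveaxis(masks, 1, -1).astype(np.float32)
    templates = np.moveaxis(
        np.stack([s.templates for s in samples]), 1, -1
    ).astype(np.float32)
    targets = np.moveaxis(
        np.stack([s.target_fd for s in samples]), 1, -1
    ).astype(np.float32) * DOSE_SCALE
    rois = np.stack([s.roi_slice[..., None] for s in samples]).astype(np.float32)
    return masks, templates, targets, rois


def train_fd(
    samples: list[FDSample], config: FDNetConfig | None = None
) -> tuple[FDNet, nn.TrainHistory]:
    """Train the field-dose network on slice samples (Adam, lr 1e-3, early
    stopping with patience 8 on a 10% validation holdout)."""
    config = config or FDNetConfig()
    model = build_fd_cnn(config)
    masks, templates, targets, rois = samples_to_arrays(samples, config)
    mu = config.mu

    def loss_fn(pred, target, roi):
        return _fd_loss_batch(pred, target, roi, mu)

    history = nn.train_network(
        model,
        inputs=(masks, templates),
        targets=(targets, rois),
        loss_fn=loss_fn,
        lr=config.lr,
        patience=config.patience,
        val_fraction=config.val_fraction,
        batch_size=config.batch_size,
        max_epochs=config.max_epochs,
        seed=config.seed,
    )
    return model, history


def evaluate_fd_loss(model: FDNet, samples: list[FDSample]) -> float:
    """Mean composite loss of a trained model on a sample set (network units)."""
    masks, templates, targets, rois = samples_to_arrays(samples, model.config)
    total, n = 0.0, 0
    for start in range(0, masks.shape[0], 16):
        sl = slice(start, start + 16)
        pred = model.forward(masks[sl], templates[sl], train=False)
        val, _ = _fd_loss_batch(pred, targets[sl], rois[sl], model.config.mu)
        total += val * (pred.shape[0])
        n += pred.shape[0]
    return total / n


def predict_field_dose(
    case: PhantomCase,
    model: FDNet,
    templates: np.ndarray,
    roi_margin_mm: float = 10.0,
) -> FieldDoseSet:
    """Predict the nine 3-D field-dose volumes (% Rx) for a case.

    Every ROI-intersecting slice is predicted and stacked; non-ROI slices
    are zero; negative outputs are clipped to zero.
    """
    from .anatomy import build_fd_samples  # local to avoid import cycle at module load

    config = model.config
    dummy_fd = np.zeros((config.out_channels,) + case.grid.shape, dtype=np.float32)
    samples = build_fd_samples(case, dummy_fd, templates, roi_margin_mm,
                               n_adjacent=3)
    out = np.zeros((config.out_channels,) + case.grid.shape, dtype=np.float32)
    if not samples:
        return FieldDoseSet(per_beam=out, grid=case.grid)
    masks, tmpl, _, _ = samples_to_arrays(samples, config)
    preds = []
    for start in range(0, masks.shape[0], 16):
        sl = slice(start, start + 16)
        preds.append(model.forward(masks[sl], tmpl[sl], train=False))
    pred = np.concatenate(preds, axis=0)
    pred = np.maximum(pred, 0.0) / DOSE_SCALE  # back to % Rx, clipped >= 0
    for s, p in zip(samples, pred):
        # the prediction is only defined inside the ROI; mask the rest
        out[:, :, :, s.query_index] = np.moveaxis(p * s.roi_slice[..., None], -1, 0)
    return FieldDoseSet(per_beam=out, grid=case.grid)
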