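"""FM-CNN: per-beam fluence-map prediction from BEV dose + PTV maps.

A compact U-Net over three resolution hierarchies (96/48/24 pixels at full
scale) with skip connections; downsampling by strided convolution,
upsampling by strided transposed convolution, Swish hidden activations, an
identity-initialized input->output skip on the dose channel, and a ReLU
output enforcing nonnegative fluence (zero-background pixels can satisfy
their target exactly and go dormant, which a strictly positive smooth
output could not).

The loss is a sign-balanced mean absolute error: plain MAE (sum over
pixels, normalized by the count of positive benchmark pixels) inflated by
``1 + lambda``, where lambda measures the imbalance between positive and
negative super-threshold errors.  A systematic over- or underestimate
therefore costs up to twice the plain MAE, pushing the mean prediction
error toward zero — fluence errors of one sign would translate into
over-/underdosing.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .bev import BEVMap
from .dose_engine import FluenceMap
from . import nn


@dataclass(frozen=True)
class FMNetConfig:
    """Architecture and training settings for the fluence-map network."""

    image_size: int = 96
    widths: tuple[int, int, int] = (16, 32, 64)
    activation: str = "swish"
    out_activation: str = "relu"   # nonnegativity activation on the output
    use_ptv_map: bool = True       # ablation flag: drop the BEV PTV input
    threshold: float = 0.001       # sign-balance threshold on the [0,1] scale
    loss_domain: str = "all"       # 'all' pixels summed, or 'positive' only
    lr: float = 1e-3
    patience: int = 15
    val_fraction: float = 0.10
    batch_size: int = 16
    max_epochs: int = 300
    seed: int = 0

    @property
    def in_channels(self) -> int:
        return 2

    @staticmethod
    def coarse(**overrides) -> "FMNetConfig":
        cfg = FMNetConfig(image_size=32, widths=(8, 16, 32), max_epochs=200,
                          batch_size=8)
        return replace(cfg, **overrides)


@dataclass
class FMSample:
    """One beam's training sample: BEV dose + BEV PTV maps -> benchmark fluence."""

    bev_dose: BEVMap
    bev_ptv: BEVMap
    target_fluence: FluenceMap

    def __post_init__(self):
        if not (
            self.bev_dose.values.shape
            == self.bev_ptv.values.shape
            == self.target_fluence.values.shape
        ):
            raise ValueError("BEV maps and fluence must share geometry")


# ---------------------------------------------------------------------------
# Loss
# ---------------------------------------------------------------------------

def fm_lambda(y_bench: np.ndarray, y_pred: np.ndarray, threshold: float = 0.001) -> float:
    """Sign-imbalance regularizer: |N(err > thr) - N(err < -thr)| / N(y_bench > 0)."""
    y_bench = np.asarray(y_bench, dtype=np.float64)
    y_pred = np.asarray(y_pred, dtype=np.float64)
    n_pos = int((y_bench > 0).sum())
    if n_pos == 0:
        raise ValueError("benchmark map has no positive pixels (lambda undefined)")
    err = y_bench - y_pred
    return float(abs(int((err > threshold).sum()) - int((err < -threshold).sum())) / n_pos)


def fm_loss(
    y_bench: np.ndarray,
    y_pred: np.ndarray,
    threshold: float = 0.001,
    domain: str = "all",
) -> float:
    """Sign-balanced MAE: ``(1 + lambda) * sum|err| / N(y_bench > 0)``.

    The sum runs over all pixels (``domain='all'``, the literal reading) or
    only over positive-benchmark pixels (``domain='positive'``).
    """
    y_bench = np.asarray(y_bench, dtype=np.float64)
    y_pred = np.asarray(y_pred, dtype=np.float64)
    lam = fm_lambda(y_bench, y_pred, threshold)
    pos = y_bench > 0
    err = np.abs(y_bench - y_pred)
    if domain == "positive":
        s = float(err[pos].sum())
    elif domain == "all":
        s = float(err.sum())
    else:
        raise ValueError(f"unknown loss domain {domain!r}")
    return (1.0 + lam) * s / int(pos.sum())


def _fm_loss_batch(pred: np.ndarray, bench: np.ndarray, threshold: float,
                   domain: str):
    """Mean per-map sign-balanced MAE over a batch with gradient wrt pred.

    lambda is piecewise constant in the prediction, so the (sub)gradient is
    ``(1 + lambda) * sign(pred - bench) / N_pos`` per map.
    """
    pred64 = pred.astype(np.float64)
    bench64 = bench.astype(np.float64)
    err = bench64 - pred64
    pos = bench64 > 0
    n_pos = pos.sum(axis=(1, 2, 3), keepdims=True)
    if np.any(n_pos == 0):
        raise ValueError("a benchmark map in the batch has no positive pixels")
    lam = (
        np.abs((err > threshold).sum(axis=(1, 2, 3), keepdims=True)
               - (err < -threshold).sum(axis=(1, 2, 3), keepdims=True))
        / n_pos
    )
    sel = np.ones_like(pred64) if domain == "all" else pos.astype(np.float64)
    n = pred.shape[0]
    per_map = (1.0 + lam) * (np.abs(err) * sel).sum(axis=(1, 2, 3), keepdims=True) / n_pos
    val = float(per_map.sum()) / n
    grad = (1.0 + lam) * np.sign(pred64 - bench64) * sel / n_pos / n
    return val, grad


# ---------------------------------------------------------------------------
# Network
# ---------------------------------------------------------------------------

class FMNet:
    """Three-hierarchy U-Net with skip connections."""

    def __init__(self, config: FMNetConfig):
        if config.image_size % 4 != 0:
            raise ValueError("image size must be divisible by 2^2")
        self.config = config
        rng = np.random.default_rng(config.seed)
        c1, c2, c3 = config.widths
        act = config.activation
        A = nn.make_activation

        self.enc1 = nn.Sequential(nn.Conv2D(config.in_channels, c1, 3, 1, rng), A(act))
        self.down1 = nn.Sequential(nn.Conv2D(c1, c2, 4, 2, rng, pad=1), A(act))
        self.enc2 = nn.Sequential(nn.Conv2D(c2, c2, 3, 1, rng), A(act))
        self.down2 = nn.Sequential(nn.Conv2D(c2, c3, 4, 2, rng, pad=1), A(act))
        self.mid = nn.Sequential(nn.Conv2D(c3, c3, 3, 1, rng), A(act))
        self.up2 = nn.Sequential(nn.ConvTranspose2D(c3, c2, rng=rng), A(act))
        self.dec2 = nn.Sequential(nn.Conv2D(2 * c2, c2, 3, 1, rng), A(act))
        self.up1 = nn.Sequential(nn.ConvTranspose2D(c2, c1, rng=rng), A(act))
        self.dec1 = nn.Sequential(nn.Conv2D(2 * c1, c1, 3, 1, rng), A(act))
        self.out = nn.Conv2D(c1, 1, 3, 1, rng)
        # input->output residual, identity-initialized on the dose channel:
        # the fluence map is to first order a rescaled BEV dose map, and the
        # live skip path keeps output gradients from dying while the U-Net
        # features are still random
        self.skip = nn.Conv2D(config.in_channels, 1, 1, 1, rng)
        self.skip.W.value[...] = 0.0
        self.skip.W.value[0, 0, 0, 0] = 1.0
        self.out_act = nn.make_activation(config.out_activation)
        self._c1, self._c2 = c1, c2

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if not self.config.use_ptv_map:
            x = x.copy()
            x[..., 1] = 0.0
        e1 = self.enc1.forward(x.astype(nn.DTYPE), train=train)
        e2 = self.enc2.forward(self.down1.forward(e1, train=train), train=train)
        m = self.mid.forward(self.down2.forward(e2, train=train), train=train)
        u2 = self.up2.forward(m, train=train)
        d2 = self.dec2.forward(np.concatenate([u2, e2], axis=3), train=train)
        u1 = self.up1.forward(d2, train=train)
        d1 = self.dec1.forward(np.concatenate([u1, e1], axis=3), train=train)
        pre = self.out.forward(d1, train=train) + self.skip.forward(x, train=train)
        return self.out_act.forward(pre, train=train)

    def backward(self, grad):
        g = self.out_act.backward(grad)
        self.skip.backward(g)  # accumulates skip weight grads; dx not needed
        g = self.out.backward(g)
        g = self.dec1.backward(g)
        g_u1, g_e1b = g[..., : self._c1], g[..., self._c1 :]
        g = self.up1.backward(np.ascontiguousarray(g_u1))
        g = self.dec2.backward(g)
        g_u2, g_e2b = g[..., : self._c2], g[..., self._c2 :]
        g = self.up2.backward(np.ascontiguousarray(g_u2))
        g = self.down2.backward(self.mid.backward(g))
        g = self.enc2.backward(g + np.ascontiguousarray(g_e2b))
        g = self.down1.backward(g)
        return self.enc1.backward(g + np.ascontiguousarray(g_e1b))

    def params(self):
        parts = (self.enc1, self.down1, self.enc2, self.down2, self.mid,
                 self.up2, self.dec2, self.up1, self.dec1, self.out, self.skip)
        return [p for part in parts for p in part.params()]

    @property
    def n_params(self) -> int:
        return nn.n_params(self)


def build_fm_cnn(config: FMNetConfig | None = None) -> FMNet:
    return FMNet(config or FMNetConfig())


@dataclass
class FMModel:
    """Trained FM network plus the cohort normalization constants.

    ``dose_norm`` scales BEV dose maps into [0,1]; ``fluence_norm`` is the
    cohort-wide benchmark-fluence scale (99.9th percentile ~ 1), recorded at
    training time and reused at inference.
    """

    net: FMNet
    dose_norm: float
    fluence_norm: float

    @property
    def config(self) -> FMNetConfig:
        return self.net.config


def _stack_inputs(bev_dose: np.ndarray, bev_ptv: np.ndarray, dose_norm: float):
    return np.stack(
        [np.asarray(bev_dose) / dose_norm, np.asarray(bev_ptv)], axis=-1
    ).astype(np.float32)


def train_fm(
    samples: list[FMSample], config: FMNetConfig | None = None
) -> tuple[FMModel, nn.TrainHistory]:
    """Train the fluence network (Adam, lr 1e-3, patience 15, 10% holdout)."""
    config = config or FMNetConfig()
    net = build_fm_cnn(config)
    doses = np.stack([s.bev_dose.values for s in samples])
    ptvs = np.stack([s.bev_ptv.values for s in samples])
    targets_raw = np.stack([s.target_fluence.values for s in samples])
    dose_norm = float(max(doses.max(), 1e-12))
    fluence_norm = float(max(np.quantile(targets_raw, 0.999), 1e-12))
    x = _stack_inputs(doses, ptvs, dose_norm)
    y = (targets_raw / fluence_norm)[..., None].astype(np.float32)

    def loss_fn(pred, target):
        return _fm_loss_batch(pred, target, config.threshold, config.loss_domain)

    history = nn.train_network(
        net,
        inputs=(x,),
        targets=(y,),
        loss_fn=loss_fn,
        lr=config.lr,
        patience=config.patience,
        val_fraction=config.val_fraction,
        batch_size=config.batch_size,
        max_epochs=config.max_epochs,
        seed=config.seed,
    )
    return FMModel(net=net, dose_norm=dose_norm, fluence_norm=fluence_norm), history


def evaluate_fm_loss(model: FMModel, samples: list[FMSample]) -> float:
    """Mean sign-balanced MAE of a trained model on a sample set ([0,1] scale)."""
    doses = np.stack([s.bev_dose.values for s in samples])
    ptvs = np.stack([s.bev_ptv.values for s in samples])
    y = (np.stack([s.target_fluence.values for s in samples])
         / model.fluence_norm)[..., None]
    x = _stack_inputs(doses, ptvs, model.dose_norm)
    total, n = 0.0, 0
    for start in range(0, x.shape[0], 16):
        sl = slice(start, start + 16)
        pred = model.net.forward(x[sl], train=False)
        val, _ = _fm_loss_batch(pred, y[sl], model.config.threshold,
                                model.config.loss_domain)
        total += val * pred.shape[0]
        n += pred.shape[0]
    return total / n


def predict_fluence(
    bev_dose: BEVMap, bev_ptv: BEVMap, model: FMModel
) -> FluenceMap:
    """Predict one beam's fluence map (raw engine units, nonnegative)."""
    x = _stack_inputs(bev_dose.values[None], bev_ptv.values[None], model.dose_norm)
    pred = model.net.forward(x, train=False)[0, ..., 0]
    return FluenceMap(
        values=pred.astype(np.float64) * model.fluence_norm,
        pixel_mm=bev_dose.pixel_mm,
        beam=bev_dose.beam,
    )


def predict_fluences(
    bev_doses: np.ndarray, bev_ptvs: np.ndarray, model: FMModel
) -> np.ndarray:
    """All-beam batched prediction; returns (n_beams, nf, nf) raw-unit values."""
    x = _stack_inputs(bev_doses, bev_ptvs, model.dose_norm)
    pred = model.net.forward(x, train=False)[..., 0]
    return pred.astype(np.float64) * model.fluence_norm
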