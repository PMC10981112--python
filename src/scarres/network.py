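"""Training protocol and inference for the 3-class scar segmenter.

Covers volume-wise cross-validation folds, LV-centered cropping and
per-image min-max normalization, paired geometric/intensity
augmentation, per-sample resolution draws for mixed-resolution
training, multi-class Dice loss with Adam, and 8-fold dihedral
test-time augmentation with the same morphological post-processing as
the reference masks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates, zoom

from .nn.unet import UNet, softmax
from .psf import FilterDesign, ResolutionSpec, apply_lowpass, calibrate_filter
from .reference import DEFAULT_FOOTPRINT, ReferenceLabels, denoise_mask

__all__ = [
    "TrainConfig",
    "FoldSplit",
    "SlicePrediction",
    "make_folds",
    "preprocess",
    "augment",
    "sample_resolution",
    "dice_loss",
    "labels_from_reference",
    "train",
    "predict_tta",
    "postprocess_labels",
]

CLASS_BACKGROUND, CLASS_MYO, CLASS_SCAR = 0, 1, 2


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters; published full-scale values noted where they
    differ from the desk-scale defaults."""

    decoder_channels: tuple[int, ...] = (32, 16, 8)  # full scale: 256..16
    lr: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    batch_size: int = 16
    epochs: int = 20  # full scale: 100
    train_resolutions_mm: tuple[float, ...] = (0.7,)
    augment: bool = True
    elastic_alpha_px: float = 3.0
    elastic_grid: int = 4
    noise_aug_sd: float = 0.02
    crop_size: int | None = None  # None: use the native slice matrix
    seed: int = 0

    def __post_init__(self):
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if not self.train_resolutions_mm:
            raise ValueError("train_resolutions_mm must be nonempty")

    @property
    def encoder_depth(self) -> int:
        return len(self.decoder_channels)


@dataclass(frozen=True)
class FoldSplit:
    fold_id: int
    train_volume_ids: tuple[int, ...]
    test_volume_ids: tuple[int, ...]


@dataclass(frozen=True)
class SlicePrediction:
    prob_maps: np.ndarray  # (3, H, W), per-pixel class probabilities
    label_mask: np.ndarray  # (H, W) int, post-processed argmax labels
    test_dx_mm: float


def make_folds(volume_ids, k: int = 5, seed: int = 0) -> list[FoldSplit]:
    """Volume-wise k-fold partition: shuffle, then split into near-equal
    test sets; every volume lands in exactly one test set."""
    vols = sorted(set(int(v) for v in volume_ids))
    if len(vols) < k:
        raise ValueError(f"need at least {k} volumes for {k} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(vols))
    shuffled = [vols[i] for i in order]
    parts = np.array_split(np.array(shuffled), k)
    folds = []
    for i, part in enumerate(parts):
        test = tuple(sorted(int(v) for v in part))
        train = tuple(sorted(v for v in vols if v not in set(test)))
        folds.append(FoldSplit(fold_id=i, train_volume_ids=train, test_volume_ids=test))
    return folds


def preprocess(
    image: np.ndarray, center: tuple[float, float] | None = None, out_size: int = 128
) -> np.ndarray:
    """Crop a square window centered at the LV and min-max normalize.

    ``center`` is the (row, col) LV centroid; defaults to the image
    center (phantom slices are already LV-centered).  A constant image
    maps to all zeros with a warning.
    """
    img = np.asarray(image, dtype=float)
    h, w = img.shape
    if h < out_size or w < out_size:
        raise ValueError("input smaller than the crop window")
    if center is None:
        cr, cc = h / 2.0, w / 2.0
    else:
        cr, cc = center
    r0 = int(round(cr)) - out_size // 2
    c0 = int(round(cc)) - out_size // 2
    r0 = min(max(r0, 0), h - out_size)
    c0 = min(max(c0, 0), w - out_size)
    crop = img[r0 : r0 + out_size, c0 : c0 + out_size]
    lo, hi = crop.min(), crop.max()
    if hi == lo:
        warnings.warn("constant image; normalized output is all zeros")
        return np.zeros_like(crop)
    return (crop - lo) / (hi - lo)


def _elastic_field(shape, grid: int, alpha: float, rng) -> tuple[np.ndarray, np.ndarray]:
    h, w = shape
    disp = rng.normal(0.0, alpha, (2, grid, grid))
    dr = zoom(disp[0], (h / grid, w / grid), order=3)
    dc = zoom(disp[1], (h / grid, w / grid), order=3)
    return dr, dc


def augment(
    image: np.ndarray,
    mask: np.ndarray,
    rng: np.random.Generator,
    elastic_alpha_px: float = 3.0,
    elastic_grid: int = 4,
    noise_sd: float = 0.02,
) -> tuple[np.ndarray, np.ndarray]:
    """Paired augmentation: elastic deformation on image and mask
    (nearest-neighbour for the mask), then intensity scaling / gamma and
    Gaussian noise on the image only."""
    img = np.asarray(image, dtype=float)
    msk = np.asarray(mask)
    rows, cols = np.meshgrid(
        np.arange(img.shape[0]), np.arange(img.shape[1]), indexing="ij"
    )
    if elastic_alpha_px > 0:
        dr, dc = _elastic_field(img.shape, elastic_grid, elastic_alpha_px, rng)
        coords = np.stack([rows + dr, cols + dc])
        img = map_coordinates(img, coords, order=1, mode="reflect")
        msk = map_coordinates(msk, coords, order=0, mode="reflect")
    mx = img.max()
    if mx > 0:
        gamma = rng.uniform(0.85, 1.18)
        gain = rng.uniform(0.9, 1.1)
        img = (np.clip(img, 0, None) / mx) ** gamma * mx * gain
        img = img + rng.normal(0.0, noise_sd * mx * rng.uniform(), img.shape)
        img = np.clip(img, 0, None)
    return img, msk


def sample_resolution(train_resolutions_mm, rng: np.random.Generator) -> float:
    """Uniform draw from the training-resolution set."""
    res = tuple(train_resolutions_mm)
    if not res:
        raise ValueError("empty resolution set")
    return float(res[rng.integers(len(res))])


def labels_from_reference(ref: ReferenceLabels) -> np.ndarray:
    """Rasterize reference masks to exclusive labels {bg, myo, scar}."""
    lab = np.zeros(ref.myo.shape, dtype=np.int64)
    lab[ref.myo & ~ref.scar] = CLASS_MYO
    lab[ref.scar] = CLASS_SCAR
    return lab


def dice_loss(
    logits: np.ndarray, labels: np.ndarray, smooth: float = 1.0
) -> tuple[float, np.ndarray]:
    """Multi-class soft Dice loss and its gradient w.r.t. the logits.

    ``logits`` is NHWC, ``labels`` is (N, H, W) integer classes.
    Per-class Dice is computed over the whole batch; the smoothing
    constant keeps classes absent from the batch well-defined.
    """
    p = softmax(logits, axis=-1)
    c = p.shape[-1]
    onehot = np.zeros_like(p)
    np.put_along_axis(onehot, labels[..., None], 1.0, axis=-1)
    inter = (p * onehot).sum(axis=(0, 1, 2))
    sums = p.sum(axis=(0, 1, 2)) + onehot.sum(axis=(0, 1, 2))
    d = (2.0 * inter + smooth) / (sums + smooth)
    loss = 1.0 - float(d.mean())
    # dL/dp_c = -(1/C) * (2 g_c - D_c) / (sums_c + smooth)
    dldp = -(2.0 * onehot - d) / ((sums + smooth) * c)
    dlogits = p * (dldp - (dldp * p).sum(axis=-1, keepdims=True))
    return loss, dlogits


def _hard_dice(pred_labels, labels, cls) -> float:
    p = pred_labels == cls
    g = labels == cls
    denom = p.sum() + g.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * (p & g).sum() / denom)


def train(slices, refs, config: TrainConfig, model: UNet | None = None):
    """Train the segmenter on native-resolution slices + reference labels.

    Per sample and epoch: draw a training resolution (degrading the
    complex image on the fly for non-native draws), augment, preprocess,
    then optimize the multi-class Dice loss with Adam.  Returns
    ``(model, log)`` where log rows carry epoch, mean loss and hard
    per-class Dice over the epoch's (augmented) training samples, plus
    the per-epoch resolution draws.
    """
    slices = list(slices)
    refs = list(refs)
    if len(slices) == 0:
        raise ValueError("need at least one training slice")
    if len(slices) != len(refs):
        raise ValueError("slices and refs length mismatch")
    rng = np.random.default_rng(config.seed)
    if model is None:
        model = UNet(
            decoder_channels=config.decoder_channels,
            seed=int(rng.integers(2**31)),
        )
    opt = model.make_optimizer(lr=config.lr, beta1=config.beta1, beta2=config.beta2)

    labels_native = [labels_from_reference(r) for r in refs]
    native_dx = slices[0].pixel_mm
    spec = ResolutionSpec(
        matrix=slices[0].image.shape[0],
        fov_mm=slices[0].image.shape[0] * native_dx,
        native_dx_mm=native_dx,
    )
    designs: dict[float, FilterDesign] = {
        dx: calibrate_filter(dx, spec) for dx in set(config.train_resolutions_mm)
    }

    log = []
    for epoch in range(config.epochs):
        order = rng.permutation(len(slices))
        epoch_losses = []
        dice_acc = {CLASS_BACKGROUND: [], CLASS_MYO: [], CLASS_SCAR: []}
        draws = []
        for start in range(0, len(order), config.batch_size):
            idx = order[start : start + config.batch_size]
            xs, ys = [], []
            for i in idx:
                dx = sample_resolution(config.train_resolutions_mm, rng)
                draws.append(dx)
                img = apply_lowpass(slices[i].image, designs[dx])
                mag = np.abs(img)
                lab = labels_native[i]
                if config.augment:
                    mag, lab = augment(
                        mag,
                        lab,
                        rng,
                        elastic_alpha_px=config.elastic_alpha_px,
                        elastic_grid=config.elastic_grid,
                        noise_sd=config.noise_aug_sd,
                    )
                xs.append(
                    preprocess(
                        mag, out_size=config.crop_size or mag.shape[0]
                    )
                )
                ys.append(lab)
            x = np.stack(xs)[..., None]  # NHWC
            y = np.stack(ys)
            logits = model.forward(x, train=True)
            loss, dlogits = dice_loss(logits, y)
            model.backward(dlogits)
            opt.step()
            epoch_losses.append(loss)
            hard = logits.argmax(axis=-1)
            for cls in dice_acc:
                dice_acc[cls].append(_hard_dice(hard, y, cls))
        log.append(
            {
                "epoch": epoch,
                "loss": float(np.mean(epoch_losses)),
                "dice_bg": float(np.mean(dice_acc[CLASS_BACKGROUND])),
                "dice_myo": float(np.mean(dice_acc[CLASS_MYO])),
                "dice_scar": float(np.mean(dice_acc[CLASS_SCAR])),
                "resolution_draws": draws,
            }
        )
    return model, log


# the eight dihedral transforms: 4 rotations x {identity, horizontal flip}
_DIHEDRAL = [(r, f) for f in (False, True) for r in range(4)]


def _transform(x: np.ndarray, r: int, f: bool) -> np.ndarray:
    if f:
        x = x[..., ::-1]
    return np.rot90(x, r, axes=(-2, -1))


def _inverse(x: np.ndarray, r: int, f: bool) -> np.ndarray:
    x = np.rot90(x, -r, axes=(-2, -1))
    if f:
        x = x[..., ::-1]
    return x


def postprocess_labels(
    labels: np.ndarray, footprint: np.ndarray = DEFAULT_FOOTPRINT
) -> np.ndarray:
    """Apply the reference-mask morphological denoising to the predicted
    scar class; scar pixels removed by it revert to myocardium."""
    out = labels.copy()
    scar = labels == CLASS_SCAR
    cleaned = denoise_mask(scar, footprint)
    out[scar & ~cleaned] = CLASS_MYO
    return out


def predict_tta(model: UNet, image: np.ndarray, test_dx_mm: float = float("nan")) -> SlicePrediction:
    """8-fold dihedral test-time augmentation.

    Predicts each transformed copy, inverts the transform on the
    probability maps, and averages; the label mask is the per-pixel
    argmax followed by the reference morphological post-processing.
    """
    img = np.asarray(image, dtype=float)
    acc = None
    for r, f in _DIHEDRAL:
        x = _transform(img, r, f)[None, ..., None]  # (1, H, W, 1)
        probs = model.predict_proba(x)[0]  # (H, W, C)
        probs = np.moveaxis(probs, -1, 0)  # (C, H, W)
        probs = _inverse(probs, r, f)
        acc = probs if acc is None else acc + probs
    prob_maps = acc / len(_DIHEDRAL)
    labels = postprocess_labels(prob_maps.argmax(axis=0))
    return SlicePrediction(
        prob_maps=prob_maps, label_mask=labels, test_dx_mm=test_dx_mm
    )
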