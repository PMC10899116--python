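"""Training: joint augmentation, the step-wise Adam schedule, and the
pixel-wise cross-entropy loop."""

from __future__ import annotations

import numpy as np
from skimage.color import hsv2rgb, rgb2hsv
from skimage.transform import AffineTransform, warp

from .config import AugmentPolicy, TrainSchedule
from .model import Network
from .nn import Adam
from .nn import functional as F

__all__ = ["augment_pair", "train_network", "macro_dice"]


def _sample_geometric(policy: AugmentPolicy, rng, size: int):
    angle = np.deg2rad(rng.uniform(-policy.max_rotation_deg,
                                   policy.max_rotation_deg))
    shift = rng.uniform(-policy.max_shift_frac, policy.max_shift_frac, 2) * size
    zoom = rng.uniform(*policy.zoom_range)
    return angle, shift, zoom


def augment_pair(patch: np.ndarray, mask: np.ndarray, policy: AugmentPolicy,
                 rng: np.random.Generator):
    """One jointly sampled geometric transform for image+mask, plus
    image-only saturation/hue jitter.

    Rotation/zoom are applied about the patch center; the image is filled by
    reflection, the mask by class 0.  Output sizes equal input sizes.  A
    policy with all ranges collapsed to the identity returns the inputs
    bit-identically.
    """
    if patch.shape[:2] != mask.shape:
        raise ValueError("patch and mask are not aligned")
    size = patch.shape[0]
    angle, shift, zoom = _sample_geometric(policy, rng, size)

    if angle != 0.0 or zoom != 1.0 or np.any(shift != 0.0):
        center = np.array([size / 2.0, size / 2.0])
        tf = (AffineTransform(translation=-center)
              + AffineTransform(rotation=angle, scale=(zoom, zoom))
              + AffineTransform(translation=center + shift[::-1]))
        inv = tf.inverse
        out_img = warp(patch.astype(np.float32), inv, order=1, mode="reflect",
                       preserve_range=True)
        out_img = np.clip(out_img, 0, 255)
        out_mask = warp(mask.astype(np.float32), inv, order=0, mode="constant",
                        cval=0, preserve_range=True).astype(mask.dtype)
    else:
        out_img = patch.astype(np.float32).copy()
        out_mask = mask.copy()

    if policy.color_aug_enabled:
        sat = rng.uniform(*policy.saturation_range)
        hue = rng.uniform(*policy.hue_range)
        if sat != 1.0 or hue != 0.0:
            hsv = rgb2hsv(out_img / 255.0)
            hsv[..., 1] = np.clip(hsv[..., 1] * sat, 0, 1)
            hsv[..., 0] = (hsv[..., 0] + hue) % 1.0
            out_img = np.clip(hsv2rgb(hsv) * 255.0, 0, 255)

    return out_img.astype(patch.dtype), out_mask


def train_network(network: Network, pairs, schedule: TrainSchedule,
                  policy: AugmentPolicy | None = None, verbose: bool = False):
    """Minimize pixel-wise cross entropy with Adam over the 3-phase schedule.

    ``pairs`` is a sequence of (image, mask) training tiles.  Returns the
    per-epoch mean loss history; the network is modified in place.  Fixed
    ``schedule.seed`` makes the shuffle/augmentation stream, and hence the
    loss trajectory, repeatable.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("training requires at least one (image, mask) pair")
    policy = policy or AugmentPolicy.identity()
    rng = np.random.default_rng(schedule.seed)
    opt = Adam(network.parameters(), lr=schedule.phase_lrs[0])
    network.train()
    history = []
    n = len(pairs)
    bs = schedule.batch_size
    for epoch in range(1, schedule.epochs + 1):
        opt.lr = schedule.lr_at(epoch)
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, bs):
            idx = order[start:start + bs]
            imgs, masks = [], []
            for i in idx:
                im, mk = augment_pair(pairs[i][0], pairs[i][1], policy, rng)
                imgs.append(im)
                masks.append(mk)
            logits = network.forward(np.stack(imgs))
            loss = F.cross_entropy(logits, np.stack(masks))
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        history.append(float(np.mean(losses)))
        if verbose:
            print(f"epoch {epoch:3d}  lr {opt.lr:.0e}  loss {history[-1]:.4f}")
    return network, history


def macro_dice(network: Network, pairs, class_ids=(1, 2, 3, 4, 5, 6)) -> float:
    """Macro-averaged Dice over the given classes, pooled across tiles."""
    from .grading import dice_coefficient
    from .model import predict_patch

    preds, truths = [], []
    for img, mask in pairs:
        _, lab = predict_patch(network, img)
        preds.append(lab.ravel())
        truths.append(mask.ravel())
    pred = np.concatenate(preds)
    truth = np.concatenate(truths)
    return float(np.mean([dice_coefficient(pred, truth, c) for c in class_ids]))
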