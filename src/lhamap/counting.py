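"""Neuron counting by regression-forest density estimation.

Instead of detecting individual somata, a random regression forest
(20 trees, maximum depth 80 by default) learns a per-pixel *density* from
the Gaussian-derivative feature bank; the count of an image or region crop
is the integral of the predicted density over its mask.  The training
target places a unit-mass Gaussian kernel (sigma_dot, default 2 px) at each
dot annotation, so the target map integrates to the annotated count.

Accuracy of a trained model is the complement of the mean relative count
error over an evaluation set:

    accuracy = 100 * (1 - mean_i |c_hat_i - c_i| / max(c_i, 1))

floored at 0.  The ``max(c, 1)`` guard keeps neuron-free tiles from
dividing by zero while still penalising spurious counts on them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .features import FeatureBankConfig, compute_features
from .synth import AnnotatedImage


def density_target(
    dots: np.ndarray, shape: Tuple[int, int], sigma_dot: float = 2.0
) -> np.ndarray:
    """Sum of unit-mass Gaussian kernels centered at the dot annotations.

    Kernels truncated by the image border are renormalized so every dot
    contributes exactly 1.0; the map therefore integrates to the number of
    dots (up to float rounding).
    """
    dots = np.asarray(dots, dtype=float).reshape(-1, 2)
    h, w = shape
    if len(dots) and (
        dots.min() < 0 or dots[:, 0].max() > h - 1 or dots[:, 1].max() > w - 1
    ):
        raise ValueError("dot outside image bounds")
    out = np.zeros(shape, dtype=np.float64)
    r = int(np.ceil(4.0 * sigma_dot))
    for row, col in dots:
        ir, ic = int(round(row)), int(round(col))
        y0, y1 = max(0, ir - r), min(h, ir + r + 1)
        x0, x1 = max(0, ic - r), min(w, ic + r + 1)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        k = np.exp(-((yy - row) ** 2 + (xx - col) ** 2) / (2.0 * sigma_dot**2))
        out[y0:y1, x0:x1] += k / k.sum()
    return out


@dataclass
class DensityModel:
    """A trained per-pixel density regressor."""

    config: FeatureBankConfig
    forest: RandomForestRegressor
    sigma_dot: float
    n_training_images: int
    seed: int

    def predict_density(self, image: np.ndarray) -> np.ndarray:
        """Predicted density map, clipped at 0 (forests can emit small negatives)."""
        feats = compute_features(image, self.config)
        h, w, c = feats.shape
        pred = self.forest.predict(feats.reshape(-1, c))
        return np.clip(pred.reshape(h, w), 0.0, None)


def _training_matrix(
    training: Sequence[AnnotatedImage],
    config: FeatureBankConfig,
    sigma_dot: float,
    rng: np.random.Generator,
    fg_threshold: float = 1e-3,
    n_background_px: int = 800,
    max_pixels_per_image: int = 20_000,
) -> Tuple[np.ndarray, np.ndarray]:
    """Stratified pixel subsample: all near-dot pixels plus random background."""
    xs, ys = [], []
    for ann in training:
        feats = compute_features(ann.image, config)
        target = density_target(ann.dots, ann.image.shape, sigma_dot)
        flat_f = feats.reshape(-1, feats.shape[-1])
        flat_t = target.ravel()
        fg_idx = np.flatnonzero(flat_t > fg_threshold)
        bg_idx = np.flatnonzero(flat_t <= fg_threshold)
        if len(bg_idx) > n_background_px:
            bg_idx = rng.choice(bg_idx, n_background_px, replace=False)
        idx = np.concatenate([fg_idx, bg_idx])
        if len(idx) > max_pixels_per_image:
            idx = rng.choice(idx, max_pixels_per_image, replace=False)
        xs.append(flat_f[idx])
        ys.append(flat_t[idx])
    return np.concatenate(xs), np.concatenate(ys)


def train_density_model(
    training: Sequence[AnnotatedImage],
    config: FeatureBankConfig | None = None,
    n_trees: int = 20,
    max_depth: int = 80,
    seed: int = 0,
    sigma_dot: float = 2.0,
) -> DensityModel:
    """Train the density counter on dot-annotated images.

    Training pixels are subsampled per image (all pixels near a dot plus a
    random background sample) to keep desk-scale runtimes; prediction is
    always full resolution.
    """
    training = list(training)
    if not training:
        raise ValueError("empty training set")
    config = config or FeatureBankConfig()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    x, y = _training_matrix(training, config, sigma_dot, rng)
    forest = RandomForestRegressor(
        n_estimators=n_trees,
        max_depth=max_depth,
        max_features=0.33,
        min_samples_leaf=2,
        random_state=int(rng.integers(2**31 - 1)),
        n_jobs=1,
    )
    forest.fit(x, y)
    return DensityModel(
        config=config,
        forest=forest,
        sigma_dot=sigma_dot,
        n_training_images=len(training),
        seed=seed,
    )


def count_image(model: DensityModel, image: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Integrated (clipped) density over ``mask`` (whole image if None)."""
    dens = model.predict_density(image)
    if mask is not None:
        if mask.shape != dens.shape:
            raise ValueError(f"mask shape {mask.shape} != image shape {dens.shape}")
        dens = dens[mask.astype(bool)]
    return float(dens.sum())


def evaluate_accuracy(
    model: DensityModel, eval_set: Sequence[AnnotatedImage]
) -> Tuple[float, pd.DataFrame]:
    """Counting accuracy (%) on dot-annotated images, with per-image errors."""
    eval_set = list(eval_set)
    if not eval_set:
        raise ValueError("empty evaluation set")
    rows = []
    for i, ann in enumerate(eval_set):
        est = count_image(model, ann.image)
        true = ann.count
        rows.append((i, true, est, abs(est - true) / max(true, 1)))
    per_image = pd.DataFrame(rows, columns=["image", "true", "estimate", "rel_error"])
    accuracy = max(0.0, 100.0 * (1.0 - per_image["rel_error"].mean()))
    return accuracy, per_image


def learning_curve(
    train_sizes: Iterable[int],
    n_eval: int,
    seeds: Sequence[int],
    simulate_kwargs: dict | None = None,
    n_trees: int = 20,
    max_depth: int = 80,
    config: FeatureBankConfig | None = None,
) -> pd.DataFrame:
    """Accuracy as a function of training-set size, per seed.

    For each seed, ``max(train_sizes) + n_eval`` annotated tiles are
    simulated; models trained on nested prefixes of the training pool are
    all evaluated on the same held-out tiles.
    """
    from .synth import simulate_training_set

    sizes = sorted(set(int(s) for s in train_sizes))
    simulate_kwargs = simulate_kwargs or {}
    rows = []
    for seed in seeds:
        pool = simulate_training_set(max(sizes) + n_eval, seed=seed, **simulate_kwargs)
        train_pool, eval_set = pool[: max(sizes)], pool[max(sizes) :]
        for size in sizes:
            model = train_density_model(
                train_pool[:size],
                config=config,
                n_trees=n_trees,
                max_depth=max_depth,
                seed=seed,
            )
            acc, _ = evaluate_accuracy(model, eval_set)
            rows.append((seed, size, acc))
    return pd.DataFrame(rows, columns=["seed", "n_train", "accuracy"])
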