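"""Foreground/background pixel classification of labeled somata.

A random-forest classifier over the shared Gaussian-derivative feature
bank separates ZsGreen-labeled somata from autofluorescent tissue and
dendritic fragments.  Training uses sparse foreground/background strokes
(pixel index sets), mirroring interactive annotation; segmentation
thresholds the predicted foreground probability (default 0.5).  Crops whose
mask comes out empty are flagged so downstream stages can drop regions
without labeled somata.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .features import FeatureBankConfig, compute_features


@dataclass
class PixelClassifier:
    config: FeatureBankConfig
    forest: RandomForestClassifier
    n_training_images: int
    seed: int
    oob_accuracy: float

    def predict_probability(self, image: np.ndarray) -> np.ndarray:
        """Per-pixel foreground probability in [0, 1]."""
        feats = compute_features(image, self.config)
        h, w, c = feats.shape
        proba = self.forest.predict_proba(feats.reshape(-1, c))[:, 1]
        return proba.reshape(h, w)


def train_pixel_classifier(
    labeled: Sequence[Tuple[np.ndarray, np.ndarray, np.ndarray]],
    config: FeatureBankConfig | None = None,
    n_trees: int = 100,
    seed: int = 0,
) -> PixelClassifier:
    """Train from sparse strokes.

    ``labeled`` is a sequence of ``(image, fg_strokes, bg_strokes)`` where
    the strokes are ``(n, 2)`` integer (row, col) arrays of annotated
    pixels.  Both classes must be present overall.
    """
    labeled = list(labeled)
    if not labeled:
        raise ValueError("no labeled images")
    config = config or FeatureBankConfig()
    xs, ys = [], []
    for image, fg, bg in labeled:
        feats = compute_features(image, config)
        for strokes, label in ((fg, 1), (bg, 0)):
            strokes = np.asarray(strokes, dtype=int).reshape(-1, 2)
            if len(strokes) == 0:
                continue
            xs.append(feats[strokes[:, 0], strokes[:, 1]])
            ys.append(np.full(len(strokes), label))
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    if len(np.unique(y)) < 2:
        raise ValueError("training strokes cover a single class; need both fg and bg")
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        random_state=seed,
        oob_score=True,
        n_jobs=1,
    )
    forest.fit(x, y)
    return PixelClassifier(
        config=config,
        forest=forest,
        n_training_images=len(labeled),
        seed=seed,
        oob_accuracy=float(forest.oob_score_),
    )


@dataclass
class SegmentationResult:
    mask: np.ndarray
    empty: bool  # no foreground found; crop can be excluded downstream


def segment(
    classifier: PixelClassifier, image: np.ndarray, threshold: float = 0.5
) -> SegmentationResult:
    """Binary foreground mask: probability >= threshold."""
    proba = classifier.predict_probability(image)
    mask = proba >= threshold
    return SegmentationResult(mask=mask, empty=not bool(mask.any()))


def strokes_from_mask(
    fg_mask: np.ndarray,
    rng: np.random.Generator,
    n_fg: int = 200,
    n_bg: int = 200,
) -> Tuple[np.ndarray, np.ndarray]:
    """Sample sparse stroke pixels from a dense truth mask (for synthetic data)."""
    fg_idx = np.argwhere(fg_mask)
    bg_idx = np.argwhere(~fg_mask)
    if len(fg_idx) > n_fg:
        fg_idx = fg_idx[rng.choice(len(fg_idx), n_fg, replace=False)]
    if len(bg_idx) > n_bg:
        bg_idx = bg_idx[rng.choice(len(bg_idx), n_bg, replace=False)]
    return fg_idx, bg_idx
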