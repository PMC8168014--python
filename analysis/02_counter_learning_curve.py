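"""Learning curve of the density counter vs training-set size.

Trains the regression-forest density counter (20 trees, depth 80) on
nested training sets of 20-250 annotated tiles and evaluates counting
accuracy on 100 held-out tiles per seed, reproducing the
accuracy-saturation behaviour of the counting workflow: steep gains up to
~100 images, a plateau beyond.

Writes results/learning_curve.csv and results/learning_curve.png.
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from lhamap.counting import learning_curve

RESULTS = Path(__file__).resolve().parent.parent / "results"
SIZES = (20, 60, 100, 150, 250)


def main() -> None:
    curve = learning_curve(SIZES, n_eval=100, seeds=(1, 2, 3))
    RESULTS.mkdir(exist_ok=True)
    curve.to_csv(RESULTS / "learning_curve.csv", index=False)

    mean = curve.groupby("n_train")["accuracy"].mean()
    print(curve.pivot(index="n_train", columns="seed", values="accuracy").round(2))
    print("\nmean accuracy by training size:")
    print(mean.round(2).to_string())

    fig, ax = plt.subplots(figsize=(5, 3.5))
    for seed, sub in curve.groupby("seed"):
        ax.plot(sub["n_train"], sub["accuracy"], "o-", alpha=0.4, label=f"seed {seed}")
    ax.plot(mean.index, mean.values, "k-", lw=2, label="mean")
    ax.set_xlabel("training images")
    ax.set_ylabel("counting accuracy (%)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(RESULTS / "learning_curve.png", dpi=150)


if __name__ == "__main__":
    main()
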