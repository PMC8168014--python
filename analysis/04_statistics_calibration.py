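"""Calibration of the two-way ANOVA + Sidak battery on simulated cohorts.

Three questions:
1. power — how often is a 1.8x expansion of the pooled orbitofrontal/
   insular projection detected at n = 6 brains per genotype?
2. specificity — do unaffected structures stay at the nominal rate?
3. family-wise error — under the null (no genotype effect, 28 structures,
   n = 3), how often does any Sidak-adjusted comparison fall below 0.05?
   This is evaluated under the ANOVA's own (homoscedastic Gaussian) error
   model, and, for comparison, under mean-dependent Poisson noise where
   the pooled-variance post-hoc is known to be anticonservative for the
   largest structures.

Writes results/calibration.json.
"""

import json
from pathlib import Path

from lhamap.stats import detection_power, family_wise_error_rate

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    power, rates = detection_power(n_reps=100, n_per_genotype=6, effect=1.8, seed=29)
    fwer = family_wise_error_rate(n_reps=500, n_per_genotype=3, seed=31)
    fwer_poisson = family_wise_error_rate(
        n_reps=200, n_per_genotype=3, seed=33, noise="poisson"
    )
    out = {
        "power_orb_ai_expansion": power,
        "max_offtarget_rate": float(rates.drop("ORBl/vl+AI").max()),
        "fwer_gaussian_null": fwer,
        "fwer_poisson_null": fwer_poisson,
    }
    RESULTS.mkdir(exist_ok=True)
    (RESULTS / "calibration.json").write_text(json.dumps(out, indent=1))
    print(json.dumps(out, indent=1))
    print(
        "\nNote: the Poisson-null FWER illustrates the anticonservatism of "
        "pooled-variance post-hoc comparisons under mean-dependent count "
        "noise (see docs/methods.md)."
    )


if __name__ == "__main__":
    main()
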