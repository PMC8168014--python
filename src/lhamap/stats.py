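"""Normalization and group statistics for projection-count tables.

Two normalizations precede the group comparisons:

* **50 k normalization** — each brain's per-structure counts are divided by
  that brain's total and rescaled to a nominal 50,000 projecting neurons,
  removing injection-efficiency variability; the normalized counts of every
  brain sum to exactly 50,000.
* **LHA atrophy compensation** — per-structure counts are multiplied by the
  ratio of the brain's LHA volume to the wild-type reference volume
  (2.75 mm³).  Composing compensation with 50 k normalization is a no-op:
  the ratio cancels.

The statistical battery mirrors common graphing-statistics practice:
fixed-effects two-way ANOVA (genotype x structure, with interaction,
Type-II sums of squares) with per-structure genotype comparisons on the
pooled residual mean square and Sidak family-wise adjustment
``p' = 1 - (1 - p)^m``; pooled-variance unpaired t-tests (raw data or
summary statistics); and one-way ANOVA with Tukey's HSD.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm


# ---------------------------------------------------------------------------
# normalizations


def normalize_50k(
    counts: Mapping[str, float], total: float | None = None, target_total: float = 50_000.0
) -> Dict[str, float]:
    """Rescale a brain's per-structure counts to a nominal brain total.

    ``out[r] = counts[r] / total * target_total``; by default ``total`` is
    the sum of the provided counts, so the output sums to ``target_total``
    exactly (up to float rounding).
    """
    vals = dict(counts)
    tot = float(sum(vals.values())) if total is None else float(total)
    if tot <= 0:
        raise ValueError("total count must be > 0 for 50k normalization")
    return {r: c / tot * target_total for r, c in vals.items()}


def atrophy_compensate(
    counts: Mapping[str, float],
    lha_volume_mm3: float,
    reference_mm3: float = 2.75,
    mode: str = "literal",
) -> Dict[str, float]:
    """Compensate counts for LHA atrophy.

    ``mode="literal"`` multiplies each count by ``lha_volume / reference``
    (counts of atrophied brains shrink); ``mode="density"`` divides by the
    ratio instead, yielding neurons per reference LHA volume.  The literal
    form is the default.
    """
    if lha_volume_mm3 <= 0 or reference_mm3 <= 0:
        raise ValueError("volumes must be > 0")
    ratio = lha_volume_mm3 / reference_mm3
    if mode == "literal":
        factor = ratio
    elif mode == "density":
        factor = 1.0 / ratio
    else:
        raise ValueError(f"unknown compensation mode {mode!r}")
    return {r: c * factor for r, c in counts.items()}


def sidak_adjust(p: float | np.ndarray, family_size: int) -> np.ndarray | float:
    """Sidak family-wise adjustment ``1 - (1 - p)^m``, clipped to [0, 1]."""
    if family_size < 1:
        raise ValueError("family_size must be >= 1")
    return np.clip(1.0 - np.power(1.0 - np.asarray(p, dtype=float), family_size), 0.0, 1.0)


# ---------------------------------------------------------------------------
# ANOVA machinery


@dataclass
class AnovaResult:
    table: pd.DataFrame  # columns: effect, F, df1, df2, p
    cell_means: pd.DataFrame
    ms_residual: float
    df_residual: float

    def effect(self, name: str) -> pd.Series:
        row = self.table[self.table["effect"] == name]
        if row.empty:
            raise KeyError(name)
        return row.iloc[0]


def _clean_anova_rows(aov: pd.DataFrame, df_resid: float) -> pd.DataFrame:
    rows = []
    total_ss = float(aov["sum_sq"].sum())
    for name, r in aov.iterrows():
        if name == "Residual":
            continue
        f, p = r["F"], r["PR(>F)"]
        # a vanishing effect SS on vanishing residual SS is "no effect"
        if not np.isfinite(f):
            if r["sum_sq"] <= 1e-10 * max(total_ss, 1.0):
                f, p = 0.0, 1.0
            else:
                f, p = np.inf, 0.0
        rows.append((name, float(f), float(r["df"]), float(df_resid), float(p)))
    return pd.DataFrame(rows, columns=["effect", "F", "df1", "df2", "p"])


def two_way_anova_sidak(
    data: pd.DataFrame,
    family_size: int | None = None,
    value: str = "value",
    genotype: str = "genotype",
    structure: str = "structure",
) -> Tuple[AnovaResult, pd.DataFrame]:
    """Two-way fixed-effects ANOVA with Sidak-adjusted per-structure tests.

    ``data`` has one row per observation with genotype, structure and value
    columns.  The ANOVA uses Type-II sums of squares with interaction (for
    a balanced layout this coincides with the classical decomposition, and
    residual df = N - (number of cells)).  Per-structure genotype
    comparisons use ``t = (mean_A - mean_B) / sqrt(MS_res (1/n_A + 1/n_B))``
    with the residual df, Sidak-adjusted over the structure family.
    """
    df = data.rename(
        columns={genotype: "genotype", structure: "structure", value: "value"}
    )[["genotype", "structure", "value"]].copy()
    genotypes = sorted(df["genotype"].unique())
    structures = sorted(df["structure"].unique())
    if len(genotypes) < 2 or len(structures) < 2:
        raise ValueError("need >= 2 genotypes and >= 2 structures")
    cells = df.groupby(["genotype", "structure"]).size()
    for g in genotypes:
        for s in structures:
            if (g, s) not in cells.index:
                raise ValueError(f"empty cell: genotype {g!r} x structure {s!r}")

    model = smf.ols("value ~ C(genotype) * C(structure)", data=df).fit()
    aov = anova_lm(model, typ=2)
    df_resid = float(model.df_resid)
    ms_res = float(model.mse_resid)
    table = _clean_anova_rows(aov, df_resid).replace(
        {
            "effect": {
                "C(genotype)": "genotype",
                "C(structure)": "structure",
                "C(genotype):C(structure)": "genotype:structure",
            }
        }
    )
    cell_means = df.groupby(["genotype", "structure"])["value"].mean().reset_index()
    result = AnovaResult(
        table=table, cell_means=cell_means, ms_residual=ms_res, df_residual=df_resid
    )

    if len(genotypes) != 2:
        raise ValueError("per-structure post-hoc comparisons need exactly 2 genotypes")
    g_a, g_b = genotypes
    m = family_size if family_size is not None else len(structures)
    rows = []
    for s in structures:
        a = df.loc[(df["genotype"] == g_a) & (df["structure"] == s), "value"].to_numpy()
        b = df.loc[(df["genotype"] == g_b) & (df["structure"] == s), "value"].to_numpy()
        diff = a.mean() - b.mean()
        se = np.sqrt(ms_res * (1.0 / len(a) + 1.0 / len(b)))
        if se == 0:
            t = 0.0 if diff == 0 else np.inf * np.sign(diff)
        else:
            t = diff / se
        p = 2.0 * sps.t.sf(abs(t), df_resid) if np.isfinite(t) else 0.0
        rows.append((s, a.mean(), b.mean(), t, p, float(sidak_adjust(p, m))))
    posthoc = pd.DataFrame(
        rows,
        columns=["structure", f"mean_{g_a}", f"mean_{g_b}", "t", "p_unadjusted", "p_sidak"],
    )
    return result, posthoc


def one_way_anova_tukey(
    groups: Mapping[str, Sequence[float]],
) -> Tuple[AnovaResult, pd.DataFrame]:
    """One-way ANOVA with Tukey's HSD on the studentized range."""
    names = sorted(groups)
    if len(names) < 2:
        raise ValueError("need >= 2 groups")
    arrays = [np.asarray(groups[n], dtype=float) for n in names]
    if any(len(a) < 2 for a in arrays):
        raise ValueError("each group needs >= 2 values")
    n_total = sum(len(a) for a in arrays)
    df1, df2 = len(names) - 1, n_total - len(names)
    grand = np.concatenate(arrays).mean()
    ss_between = sum(len(a) * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    ms_res = ss_within / df2
    if ss_between <= 1e-10 * max(ss_between + ss_within, 1.0):
        f, p = 0.0, 1.0
    elif ms_res == 0:
        f, p = np.inf, 0.0
    else:
        f = (ss_between / df1) / ms_res
        p = float(sps.f.sf(f, df1, df2))
    table = pd.DataFrame(
        [("group", float(f), float(df1), float(df2), float(p))],
        columns=["effect", "F", "df1", "df2", "p"],
    )
    cell_means = pd.DataFrame(
        {"group": names, "value": [a.mean() for a in arrays]}
    )
    result = AnovaResult(
        table=table, cell_means=cell_means, ms_residual=float(ms_res), df_residual=float(df2)
    )
    tk = sps.tukey_hsd(*arrays)
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            rows.append(
                (
                    f"{names[i]} vs {names[j]}",
                    arrays[i].mean() - arrays[j].mean(),
                    float(tk.statistic[i, j]),
                    float(tk.pvalue[i, j]),
                )
            )
    posthoc = pd.DataFrame(rows, columns=["pair", "mean_diff", "q_stat", "p_tukey"])
    return result, posthoc


# ---------------------------------------------------------------------------
# t-tests


def unpaired_t(
    values_a: Sequence[float], values_b: Sequence[float], two_tailed: bool = True
) -> Tuple[float, float, float]:
    """Two-sample pooled-variance Student t-test; returns (t, df, p)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 values")
    return pooled_t_from_summary(
        a.mean(), a.std(ddof=1), len(a), b.mean(), b.std(ddof=1), len(b), two_tailed
    )


def pooled_t_from_summary(
    mean1: float,
    sd1: float,
    n1: int,
    mean2: float,
    sd2: float,
    n2: int,
    two_tailed: bool = True,
) -> Tuple[float, float, float]:
    """Pooled-variance Student t-test from summary statistics.

    ``sp² = ((n1-1) sd1² + (n2-1) sd2²) / (n1+n2-2)``,
    ``t = (m1-m2) / (sp sqrt(1/n1 + 1/n2))``, df = n1+n2-2.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 in each group")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be >= 0")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    if sp2 == 0:
        t = 0.0 if mean1 == mean2 else np.inf * np.sign(mean1 - mean2)
    else:
        t = (mean1 - mean2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    if np.isfinite(t):
        p = sps.t.sf(abs(t), df)
        p = 2.0 * p if two_tailed else p
    else:
        p = 0.0
    return float(t), float(df), float(p)


# ---------------------------------------------------------------------------
# calibration of the two-way battery on simulated cohorts


def family_wise_error_rate(
    n_reps: int = 500,
    n_per_genotype: int = 3,
    seed: int = 0,
    alpha: float = 0.05,
    noise: str = "gaussian",
) -> float:
    """Fraction of null cohorts with any Sidak-adjusted p below ``alpha``.

    Cohorts are simulated with no genotype effect under the ANOVA's own
    error model (``noise="gaussian"``) from the default 28-structure count
    profile; ``noise="poisson"`` exposes the anticonservatism of the pooled
    residual variance under mean-dependent count noise.
    """
    from .synth import simulate_structure_counts

    root = np.random.SeedSequence(seed)
    hits = 0
    for child in root.spawn(n_reps):
        rep_seed = int(child.generate_state(1, np.uint32)[0])
        data = simulate_structure_counts(n_per_genotype, seed=rep_seed, noise=noise)
        _, posthoc = two_way_anova_sidak(data)
        if (posthoc["p_sidak"] < alpha).any():
            hits += 1
    return hits / n_reps


def detection_power(
    n_reps: int = 100,
    n_per_genotype: int = 6,
    effect: float = 1.8,
    target_structure: str = "ORBl/vl+AI",
    effect_genotype: str = "mSOD1",
    seed: int = 0,
    alpha: float = 0.05,
    noise: str = "gaussian",
) -> Tuple[float, pd.Series]:
    """Detection rate of a multiplicative projection expansion.

    Returns ``(power, per_structure_rates)`` where power is the fraction of
    simulated cohorts in which the expanded structure reaches Sidak-adjusted
    significance, and the series gives each structure's detection rate.
    """
    from .synth import simulate_structure_counts

    root = np.random.SeedSequence(seed)
    rates: Dict[str, int] = {}
    for child in root.spawn(n_reps):
        rep_seed = int(child.generate_state(1, np.uint32)[0])
        data = simulate_structure_counts(
            n_per_genotype,
            seed=rep_seed,
            effect_map={(effect_genotype, target_structure): effect},
            noise=noise,
        )
        _, posthoc = two_way_anova_sidak(data)
        sig = posthoc.loc[posthoc["p_sidak"] < alpha, "structure"]
        for s in posthoc["structure"]:
            rates.setdefault(s, 0)
        for s in sig:
            rates[s] += 1
    per_structure = pd.Series({s: h / n_reps for s, h in rates.items()}).sort_index()
    return float(per_structure.get(target_structure, 0.0)), per_structure
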