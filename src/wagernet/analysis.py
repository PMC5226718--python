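"""Behavioral statistics of the uncertain-option task.

Works on the tidy trial tables produced by
:func:`wagernet.trials.run_ensemble`: psychometric functions, the
conditional sure-choice map P(S | nu_L, nu_R), its one-dimensional
projections, decision-time bimodality and the fast/slow split,
bootstrap comparison of error counts, the X-pattern of sure choices in
early correct vs early error trials (simulated and closed-form), the
reward trade-off, and phase-plane rate distributions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AnalysisParams",
    "wilson_interval",
    "psychometrics",
    "conditional_sure_map",
    "sure_probability_projections",
    "dt_split",
    "bootstrap_error_counts",
    "xpattern_simulated",
    "xpattern_probabilistic",
    "reward_amount",
    "reward_from_trials",
    "rate_distributions",
]

CONDITION_KEYS = ["lam", "dlam", "duration"]


@dataclass(frozen=True)
class AnalysisParams:
    """Settings of the derived statistics.

    ``bin_side`` is the phase-plane bin (1 Hz); bins with fewer than
    ``low_count`` trials (30) are masked; the DT histogram dip is
    searched in ``dt_range`` ([100, 1500] ms); bootstrap uses ``B``
    (10000) resamples; the sure target is worth ``w_S`` (0.8) of a
    correct choice.
    """

    bin_side: float = 1.0
    snapshot_window: float = 50.0
    low_count: int = 30
    dt_range: tuple[float, float] = (100.0, 1500.0)
    dt_bin: float = 10.0
    B: int = 10000
    w_S: float = 0.8

    def __post_init__(self) -> None:
        if min(self.bin_side, self.snapshot_window, self.low_count,
               self.dt_bin, self.B, self.w_S) <= 0:
            raise ValueError("analysis parameters must be positive")


def wilson_interval(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    if n == 0:
        return (math.nan, math.nan)
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    p = k / n
    denom = 1.0 + z * z / n
    centre = (p + z * z / (2 * n)) / denom
    half = z * math.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
    return (max(0.0, centre - half), min(1.0, centre + half))


def _prop(series: pd.Series) -> tuple[float, int, tuple[float, float]]:
    n = int(series.shape[0])
    k = int(series.sum())
    p = k / n if n else math.nan
    return p, n, wilson_interval(k, n)


def psychometrics(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-condition choice probabilities.

    For each (lam, dlam, duration): P(correct) in forced-choice
    trials; P(correct) among free-choice trials in which the sure
    target was shown but waived (final choice not S); P(S) among
    free-choice trials.  Undecided trials are excluded from the
    correct-rate denominators.  Wilson 95% intervals accompany every
    proportion; empty cells yield NaN.
    """
    rows = []
    for key, grp in trials.groupby(CONDITION_KEYS):
        lam, dlam, duration = key
        row: dict = {"lam": lam, "dlam": dlam, "duration": duration}

        forced = grp[(~grp.free_choice)
                     & grp.final_choice.isin(["L", "R"])]
        p, n, ci = _prop(forced.correct) if len(forced) else (math.nan, 0, (math.nan,) * 2)
        row.update(p_correct_forced=p, n_forced=n,
                   ci_correct_forced_lo=ci[0], ci_correct_forced_hi=ci[1])

        free = grp[grp.free_choice]
        waived = free[free.final_choice.isin(["L", "R"])]
        p, n, ci = _prop(waived.correct) if len(waived) else (math.nan, 0, (math.nan,) * 2)
        row.update(p_correct_waived=p, n_waived=n,
                   ci_correct_waived_lo=ci[0], ci_correct_waived_hi=ci[1])

        decided_free = free[free.final_choice != "undecided"]
        if len(decided_free):
            p, n, ci = _prop(decided_free.final_choice == "S")
        else:
            p, n, ci = math.nan, 0, (math.nan, math.nan)
        row.update(p_sure=p, n_free=n, ci_sure_lo=ci[0], ci_sure_hi=ci[1])
        rows.append(row)
    return pd.DataFrame(rows).sort_values(CONDITION_KEYS).reset_index(drop=True)


def _snapshot_bins(trials: pd.DataFrame, side: float):
    ix = np.floor(trials.rate_L.to_numpy() / side).astype(int)
    iy = np.floor(trials.rate_R.to_numpy() / side).astype(int)
    return ix, iy


def conditional_sure_map(trials: pd.DataFrame,
                         params: AnalysisParams | None = None) -> pd.DataFrame:
    """P(S | nu_L, nu_R): sure-choice probability per phase-plane bin.

    Free-choice trials are pooled (all conditions by default); the
    plane of pre-sure-onset rate snapshots is divided in square bins of
    ``bin_side`` (1 Hz); each bin reports the fraction of its trials
    that ended in a sure choice; bins with fewer than ``low_count``
    (30) trials are masked (``low_count_mask``).
    """
    params = params or AnalysisParams()
    free = trials[trials.free_choice & (trials.final_choice != "undecided")]
    ix, iy = _snapshot_bins(free, params.bin_side)
    sure = (free.final_choice == "S").to_numpy()
    df = pd.DataFrame({"ix": ix, "iy": iy, "sure": sure})
    agg = df.groupby(["ix", "iy"]).agg(n=("sure", "size"), k=("sure", "sum"))
    agg = agg.reset_index()
    agg["nu_L"] = (agg.ix + 0.5) * params.bin_side
    agg["nu_R"] = (agg.iy + 0.5) * params.bin_side
    agg["p_sure"] = agg.k / agg.n
    agg["low_count_mask"] = agg.n < params.low_count
    return agg[["nu_L", "nu_R", "n", "p_sure", "low_count_mask"]]


def sure_probability_projections(trials: pd.DataFrame,
                                 n_bins: int = 12) -> dict[str, pd.DataFrame]:
    """1 - P(S) against |nu_L - nu_R| and against nu_L + nu_R.

    Returns one binned curve per projection with an isotonic-fit
    residual (fraction of the curve's range) quantifying how close
    each is to a monotone sigmoid-like increase.
    """
    from sklearn.isotonic import IsotonicRegression

    free = trials[trials.free_choice & (trials.final_choice != "undecided")]
    not_sure = (free.final_choice != "S").to_numpy(dtype=float)
    out = {}
    for name, x in (("abs_diff", np.abs(free.rate_L - free.rate_R).to_numpy()),
                    ("sum", (free.rate_L + free.rate_R).to_numpy())):
        edges = np.quantile(x, np.linspace(0, 1, n_bins + 1))
        edges = np.unique(edges)
        which = np.clip(np.digitize(x, edges) - 1, 0, len(edges) - 2)
        curve = pd.DataFrame({
            "x": [x[which == b].mean() for b in range(len(edges) - 1)],
            "one_minus_p_sure": [not_sure[which == b].mean()
                                 for b in range(len(edges) - 1)],
            "n": [int((which == b).sum()) for b in range(len(edges) - 1)],
        }).dropna()
        iso = IsotonicRegression(increasing=True)
        fit = iso.fit_transform(curve.x, curve.one_minus_p_sure)
        rng = np.ptp(curve.one_minus_p_sure.to_numpy())
        resid = (np.abs(fit - curve.one_minus_p_sure).mean() / rng
                 if rng > 0 else 0.0)
        curve.attrs["isotonic_residual"] = float(resid)
        out[name] = curve
    return out


def dt_split(trials: pd.DataFrame,
             params: AnalysisParams | None = None
             ) -> tuple[float, pd.DataFrame, pd.DataFrame, bool]:
    """Split decided trials into fast and slow at the DT histogram dip.

    The decision-time histogram (10 ms bins, 3-bin moving average) is
    searched for its minimum inside ``dt_range`` ([100, 1500] ms); the
    trials are partitioned at that point.  Returns (split point, fast
    table, slow table, no_interior_dip flag); the flag is raised when
    the minimum sits at the search-range boundary or lacks a higher
    shoulder on either side (a unimodal histogram).
    """
    params = params or AnalysisParams()
    decided = trials.dropna(subset=["decision_time"])
    # sure-choice trials leave the direction competition and do not
    # enter the decision-time distribution
    decided = decided[decided.final_choice != "S"]
    dts = decided.decision_time.to_numpy()
    if dts.size == 0:
        raise ValueError("no decided trials with a decision time")
    lo, hi = params.dt_range
    edges = np.arange(0.0, max(dts.max(), hi) + params.dt_bin, params.dt_bin)
    counts, _ = np.histogram(dts, bins=edges)
    smooth = np.convolve(counts, np.ones(3) / 3.0, mode="same")
    centers = 0.5 * (edges[:-1] + edges[1:])
    # A valid dip separates non-trivial mass on both sides; without
    # this constraint the minimum lands in an empty tail that happens
    # to intersect the search range.
    frac_left = np.cumsum(counts) / dts.size
    eligible = np.flatnonzero((centers >= lo) & (centers <= hi)
                              & (frac_left >= 0.05) & (frac_left <= 0.95))
    in_range = (eligible if eligible.size
                else np.flatnonzero((centers >= lo) & (centers <= hi)))
    k = in_range[np.argmin(smooth[in_range])]
    split = centers[k]

    at_edge = k in (in_range[0], in_range[-1])
    left_peak = smooth[:k].max() if k > 0 else 0.0
    right_peak = smooth[k + 1:].max() if k + 1 < smooth.size else 0.0
    no_dip = bool(at_edge or left_peak <= smooth[k] or right_peak <= smooth[k])

    fast = decided[decided.decision_time < split]
    slow = decided[decided.decision_time >= split]
    return float(split), fast, slow, no_dip


def bootstrap_error_counts(fast: pd.DataFrame, slow: pd.DataFrame,
                           B: int = 10000, seed: int = 0
                           ) -> dict:
    """Bootstrap distributions of the number of error trials.

    Each of ``B`` resamples draws trials with replacement within the
    fast and the slow set and counts errors; a two-sample t-test
    compares the two bootstrap distributions.
    """
    if len(fast) == 0 or len(slow) == 0:
        raise ValueError("both fast and slow sets must be non-empty")
    rng = np.random.default_rng(seed)
    out = {}
    for name, df in (("fast", fast), ("slow", slow)):
        errors = (~df.correct.to_numpy(dtype=bool)).astype(np.int64)
        idx = rng.integers(0, errors.size, size=(B, errors.size))
        out[name] = errors[idx].sum(axis=1)
    t, p = stats.ttest_ind(out["fast"], out["slow"], equal_var=False)
    out["t_stat"] = float(t)
    out["p_value"] = float(p)
    return out


def xpattern_simulated(trials: pd.DataFrame) -> pd.DataFrame:
    """P(S | early correct) and P(S | early error) against delta_lambda.

    Conditions on the early (pre-sure-onset) direction choice of
    free-choice trials; conditions with no early errors yield NaN and
    are flagged via the count columns.
    """
    free = trials[trials.free_choice & trials.early_choice.isin(["L", "R"])
                  & (trials.final_choice != "undecided")].copy()
    free["early_correct"] = free.early_choice == "L"
    rows = []
    for dlam, grp in free.groupby("dlam"):
        row = {"dlam": dlam}
        for label, sub in (("correct", grp[grp.early_correct]),
                           ("error", grp[~grp.early_correct])):
            if len(sub):
                p, n, ci = _prop(sub.final_choice == "S")
            else:
                p, n, ci = math.nan, 0, (math.nan, math.nan)
            row.update({f"p_sure_{label}": p, f"n_{label}": n,
                        f"ci_{label}_lo": ci[0], f"ci_{label}_hi": ci[1]})
        rows.append(row)
    return pd.DataFrame(rows).sort_values("dlam").reset_index(drop=True)


def xpattern_probabilistic(P_C: float, P_S: float, P_C_given_waived: float
                           ) -> tuple[float, float]:
    """Closed-form P(S|C), P(S|E) from behavioral probabilities.

    Derived from Bayes' theorem under the single assumption that
    showing the sure target does not change the overall probability of
    a correct decision:

        P(S|C) = [P(C) - P(C|S̄) + P(S) P(C|S̄)] / P(C)
        P(S|E) = 1 - P(E|S̄) P(S̄) / P(E)

    Degenerate denominators (P(C) = 0 or P(E) = 0) yield NaN.
    """
    for v in (P_C, P_S, P_C_given_waived):
        if not 0.0 <= v <= 1.0:
            raise ValueError("probabilities must lie in [0, 1]")
    if P_C > 0:
        p_s_c = (P_C - P_C_given_waived + P_S * P_C_given_waived) / P_C
    else:
        p_s_c = math.nan
    P_E = 1.0 - P_C
    if P_E > 0:
        p_s_e = 1.0 - (1.0 - P_C_given_waived) * (1.0 - P_S) / P_E
    else:
        p_s_e = math.nan
    return p_s_c, p_s_e


def reward_amount(P_C: float, P_S: float, w_S: float = 0.8) -> float:
    """Mean reward per trial: P(correct) + P(sure) * w_S."""
    return P_C + P_S * w_S


def reward_from_trials(trials: pd.DataFrame, w_S: float = 0.8) -> float:
    """Per-trial reward accumulation (error 0, correct 1, sure w_S)."""
    free = trials[trials.final_choice != "undecided"]
    if len(free) == 0:
        return math.nan
    values = np.where(free.final_choice == "S", w_S,
                      np.where(free.correct, 1.0, 0.0))
    return float(values.mean())


def rate_distributions(trials: pd.DataFrame,
                       grouping: list[str] | None = None,
                       params: AnalysisParams | None = None) -> pd.DataFrame:
    """Normalized 2D histograms of the (nu_L, nu_R) snapshots.

    Grouped by condition (default) or by early correct/error; each row
    is one occupied bin with its probability mass.  The per-group
    diagonal asymmetry (signed mass difference across nu_L = nu_R) and
    mean |nu_L - nu_R| are attached as group summary columns.
    """
    params = params or AnalysisParams()
    grouping = grouping or CONDITION_KEYS
    work = trials.dropna(subset=["rate_L", "rate_R"]).copy()
    if "early_correct" in grouping and "early_correct" not in work.columns:
        work = work[work.early_choice.isin(["L", "R"])]
        work["early_correct"] = work.early_choice == "L"
    rows = []
    for key, grp in work.groupby(grouping):
        key = key if isinstance(key, tuple) else (key,)
        ix, iy = _snapshot_bins(grp, params.bin_side)
        df = pd.DataFrame({"ix": ix, "iy": iy})
        agg = df.groupby(["ix", "iy"]).size().reset_index(name="n")
        total = agg.n.sum()
        diff = grp.rate_L - grp.rate_R
        asym = float((diff > 0).mean() - (diff < 0).mean())
        for _, b in agg.iterrows():
            rows.append({
                **dict(zip(grouping, key)),
                "nu_L": (b.ix + 0.5) * params.bin_side,
                "nu_R": (b.iy + 0.5) * params.bin_side,
                "prob": b.n / total,
                "n": int(b.n),
                "diag_asymmetry": asym,
                "mean_abs_diff": float(np.abs(diff).mean()),
            })
    return pd.DataFrame(rows)
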