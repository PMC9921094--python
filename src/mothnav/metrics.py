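"""Evaluation metrics and behavioral analysis.

Implements the study's evaluation indices — success rate, localization
time, crosswind RMSE — and the frequency-binned velocity analysis with
piecewise-affine parameter recovery that closes the loop back to the
controller's modulation law.

The crosswind RMSE of a trajectory of n logged steps is

    RMSE = sqrt( (1/n) * sum_i (y_i - y_odor)^2 )    [m]

measuring how much the agent meandered off the odor-source line; small
values mean it moved smoothly inside the plume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .agent_sim import TrialResult
from .controllers import GainTable

__all__ = [
    "BatchSummary",
    "ModulationCurve",
    "BranchFit",
    "PiecewiseGainFit",
    "crosswind_rmse",
    "trial_rmse",
    "summarize_batch",
    "compare_success_counts",
    "compare_rank_sum",
    "modulation_curves",
    "fit_piecewise_gains",
]


def crosswind_rmse(trajectory, y_odor: float = 0.0) -> float:
    """Root-mean-square crosswind deviation (m) over every logged step.

    ``trajectory`` may be a 1-D array of y-coordinates or an (n, >=3) array
    with columns (t, x, y, ...) as produced by the trial runner.
    """
    arr = np.asarray(trajectory, dtype=float)
    if arr.ndim == 2:
        arr = arr[:, 2]
    if arr.size == 0:
        raise ValueError("empty trajectory")
    return float(np.sqrt(np.mean((arr - y_odor) ** 2)))


def trial_rmse(result: TrialResult) -> float:
    """Crosswind RMSE of a trial, using the cached sums if the full
    trajectory was not recorded."""
    if result.trajectory.size:
        return crosswind_rmse(result.trajectory, result.y_odor)
    if result.n_steps == 0:
        raise ValueError("empty trajectory")
    return math.sqrt(result.crosswind_sumsq / result.n_steps)


@dataclass
class BatchSummary:
    """Aggregate outcome statistics of one (algorithm, scenario) batch."""

    algorithm: str
    scenario: str
    n_trials: int
    n_success: int
    localization_times: list[float]   # successful trials only, s
    rmse_values: list[float]          # every trial, m

    @property
    def success_rate(self) -> float:
        return self.n_success / self.n_trials

    def to_row(self) -> dict:
        times = self.localization_times
        return {
            "algorithm": self.algorithm,
            "scenario": self.scenario,
            "n_trials": self.n_trials,
            "n_success": self.n_success,
            "success_rate": self.success_rate,
            "median_time_s": float(np.median(times)) if times else float("nan"),
            "mean_rmse_m": float(np.mean(self.rmse_values)),
        }


def summarize_batch(results: list[TrialResult], algorithm: str = "",
                    scenario: str = "") -> BatchSummary:
    """Reduce a batch of trials to counts, times and per-trial RMSE."""
    if not results:
        raise ValueError("need at least one trial result")
    times = [r.localization_time for r in results if r.success]
    return BatchSummary(
        algorithm=algorithm,
        scenario=scenario,
        n_trials=len(results),
        n_success=sum(r.success for r in results),
        localization_times=times,
        rmse_values=[trial_rmse(r) for r in results],
    )


def compare_success_counts(summary1: BatchSummary,
                           summary2: BatchSummary) -> float:
    """Two-sided Fisher's exact test on the 2x2 success/failure table."""
    table = [[summary1.n_success, summary1.n_trials - summary1.n_success],
             [summary2.n_success, summary2.n_trials - summary2.n_success]]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def compare_rank_sum(values1, values2) -> float:
    """Two-sided Mann-Whitney rank-sum p-value (distribution comparison hook
    for localization times / RMSE)."""
    return float(stats.mannwhitneyu(values1, values2,
                                    alternative="two-sided")[1])


@dataclass
class ModulationCurve:
    """Frequency-binned median velocities for one search mode.

    ``table`` has one row per populated bin: bin_left, bin_right, f_median,
    v_median (mm/s), w_abs_median (rad/s), n_samples.  Bins with no samples
    are simply absent.
    """

    mode: str
    table: pd.DataFrame

    def __len__(self) -> int:
        return len(self.table)


def modulation_curves(stimulus_logs, bin_width: float = 0.1,
                      modes: tuple[str, ...] = ("active", "inactive"),
                      ) -> dict[str, ModulationCurve]:
    """Bin per-tick (f, v, |w|) samples by odor frequency, per mode.

    ``stimulus_logs`` is a DataFrame with columns f, mode, v_cmd, w_cmd (as
    written by the trial runner), or a list of such frames.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    if isinstance(stimulus_logs, (list, tuple)):
        frames = [lg if isinstance(lg, pd.DataFrame) else pd.DataFrame(lg)
                  for lg in stimulus_logs]
        df = (pd.concat(frames, ignore_index=True) if frames
              else pd.DataFrame(columns=["f", "mode", "v_cmd", "w_cmd"]))
    else:
        df = stimulus_logs

    out: dict[str, ModulationCurve] = {}
    for mode in modes:
        sub = df[df["mode"] == mode]
        if len(sub) == 0:
            out[mode] = ModulationCurve(mode, pd.DataFrame(
                columns=["bin_left", "bin_right", "f_median", "v_median",
                         "w_abs_median", "n_samples"]))
            continue
        idx = np.floor(sub["f"].to_numpy() / bin_width).astype(int)
        rows = []
        for b in np.unique(idx):
            sel = sub[idx == b]
            rows.append({
                "bin_left": b * bin_width,
                "bin_right": (b + 1) * bin_width,
                "f_median": float(sel["f"].median()),
                "v_median": float(sel["v_cmd"].median()),
                "w_abs_median": float(sel["w_cmd"].abs().median()),
                "n_samples": int(len(sel)),
            })
        out[mode] = ModulationCurve(mode, pd.DataFrame(rows))
    return out


@dataclass
class BranchFit:
    """Least-squares affine fit v = a*f + b for one frequency branch."""

    a: float
    b: float
    se_a: float
    se_b: float
    n_bins: int

    @property
    def ok(self) -> bool:
        return self.n_bins >= 2


def _fit_branch(x: np.ndarray, y: np.ndarray) -> BranchFit | None:
    """OLS line through the (f, median) points of one branch; None if
    underdetermined (< 2 distinct abscissae)."""
    if x.size < 2 or np.unique(x).size < 2:
        return None
    X = np.column_stack([x, np.ones_like(x)])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    dof = max(x.size - 2, 1)
    s2 = float(resid @ resid) / dof
    xc = x - x.mean()
    sxx = float(xc @ xc)
    se_a = math.sqrt(s2 / sxx) if sxx > 0 else float("inf")
    se_b = math.sqrt(s2 * (1.0 / x.size + x.mean() ** 2 / sxx)) if sxx > 0 \
        else float("inf")
    return BranchFit(float(coef[0]), float(coef[1]), se_a, se_b, x.size)


@dataclass
class PiecewiseGainFit:
    """Recovered modulation-law coefficients for one mode.

    ``v_low``/``v_high`` fit K_v on the f <= breakpoint / f > breakpoint
    branches, ``w_low``/``w_high`` likewise for |K_w|.  A branch with fewer
    than two populated bins is withheld (None) rather than extrapolated.
    """

    mode: str
    breakpoint: float
    v_low: BranchFit | None
    v_high: BranchFit | None
    w_low: BranchFit | None
    w_high: BranchFit | None


def fit_piecewise_gains(curve: ModulationCurve,
                        breakpoint: float = GainTable.breakpoint
                        ) -> PiecewiseGainFit:
    """Recover (a, b) per branch from a binned modulation curve.

    Each branch (f <= breakpoint, f > breakpoint) is fitted independently by
    ordinary least squares on the per-bin median frequency vs the per-bin
    median velocity; noiseless samples generated from the affine law are
    recovered to numerical precision.
    """
    t = curve.table
    if len(t) == 0:
        return PiecewiseGainFit(curve.mode, breakpoint, None, None, None, None)
    f = t["f_median"].to_numpy(dtype=float)
    low = f <= breakpoint
    fits = {}
    for key, col in (("v", "v_median"), ("w", "w_abs_median")):
        y = t[col].to_numpy(dtype=float)
        fits[key + "_low"] = _fit_branch(f[low], y[low])
        fits[key + "_high"] = _fit_branch(f[~low], y[~low])
    return PiecewiseGainFit(curve.mode, breakpoint, fits["v_low"],
                            fits["v_high"], fits["w_low"], fits["w_high"])
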