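"""From trial records to result surfaces: weight maps, trends, pre/post tests.

The pipeline mirrors the experimental logic: estimate one (w_t, w_d)
pair per judgment trial with the constrained vector-sum solver, average
within design cells (central slant x central tilt x discrepancy) per
subject and phase, fit the log-slant trend of the disparity weight with
per-tilt offsets, and compare pre- vs post-training weights cell-wise.

Inference is fully implemented rather than delegated: the trend fit is
ordinary least squares with a subject-level bootstrap for interval
estimates, and the pre/post comparison is a paired sign-flip permutation
test on per-subject cell differences with max-T family-wise correction
over the 3 x 3 cell grid of each discrepancy condition.  A scale note:
monotone re-expressions of the weight (such as reflecting it about a
constant to fix a skewed model family) change neither the cell means'
ordering nor the permutation tests, so none is applied here.

Trials where the two cue normals are (near-)parallel have unidentifiable
weights; they are flagged by the solver, excluded from cell means, and
counted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .geometry import normal_from_orientation
from .cue_weights import estimate_batch

__all__ = [
    "CELL_KEYS",
    "WeightMap",
    "TrendFit",
    "PrePostResult",
    "estimate_trial_weights",
    "aggregate",
    "fit_trend",
    "pre_post_test",
]

#: Columns identifying one design cell.
CELL_KEYS = ["delta_sigma", "delta_tau", "sigma_c", "tau_c"]


def estimate_trial_weights(records: pd.DataFrame) -> pd.DataFrame:
    """Append per-trial weight estimates to a trial table.

    Expects columns sigma_c, tau_c, delta_sigma, delta_tau and the
    perceived orientation (perceived_slant, perceived_tilt).  Adds
    w_t, w_d, residual_norm, degenerate and converged.  Solver flags
    propagate per row; the batch never aborts.
    """
    df = records.copy()
    sig = df["sigma_c"].to_numpy(dtype=float)
    tau = df["tau_c"].to_numpy(dtype=float)
    ds = df["delta_sigma"].to_numpy(dtype=float)
    dt = df["delta_tau"].to_numpy(dtype=float)
    n_d = normal_from_orientation((sig - ds / 2, tau - dt / 2))
    n_t = normal_from_orientation((sig + ds / 2, tau + dt / 2))
    n_p = normal_from_orientation(
        (df["perceived_slant"].to_numpy(dtype=float),
         df["perceived_tilt"].to_numpy(dtype=float))
    )
    est = estimate_batch(n_p, n_t, n_d)
    df["w_t"] = est["w_t"]
    df["w_d"] = est["w_d"]
    df["residual_norm"] = est["residual_norm"]
    df["degenerate"] = est["degenerate"]
    df["converged"] = est["converged"]
    return df


@dataclass(frozen=True)
class WeightMap:
    """Cell-level weight summaries.

    ``per_subject`` has one row per (cell, phase, subject) with mean and
    SD of w_d/w_t and the number of contributing trials; ``pooled``
    averages the per-subject means within (cell, phase).  ``n_dropped``
    counts degenerate trials excluded from the means.
    """

    per_subject: pd.DataFrame
    pooled: pd.DataFrame
    n_dropped: int


def aggregate(records: pd.DataFrame) -> WeightMap:
    """Cell means of the estimated weights, per subject and pooled."""
    if "w_d" not in records.columns:
        raise ValueError("run estimate_trial_weights first")
    ok = records.loc[~records["degenerate"].astype(bool)]
    n_dropped = int(len(records) - len(ok))
    keys = CELL_KEYS + ["phase", "subject_id"]
    per_subject = (
        ok.groupby(keys, as_index=False)
        .agg(
            w_d=("w_d", "mean"),
            w_t=("w_t", "mean"),
            w_d_sd=("w_d", "std"),
            n=("w_d", "size"),
        )
    )
    pooled = (
        per_subject.groupby(CELL_KEYS + ["phase"], as_index=False)
        .agg(w_d=("w_d", "mean"), w_t=("w_t", "mean"), n_subjects=("w_d", "size"))
    )
    return WeightMap(per_subject=per_subject, pooled=pooled, n_dropped=n_dropped)


@dataclass(frozen=True)
class TrendFit:
    """OLS fit of w_d on log slant with per-tilt intercept offsets.

    ``tilt_offsets`` maps each non-reference tilt to its additive offset
    relative to the lowest tilt.  ``slope_ci`` is the 2.5-97.5 percentile
    interval of the subject-bootstrap slope distribution.
    """

    slope: float
    intercept: float
    tilt_offsets: dict[float, float]
    slope_se: float
    slope_ci: tuple[float, float]
    n_boot: int
    boot_slopes: np.ndarray = dc_field(repr=False, default=None)


def _ols_trend(cells: pd.DataFrame, tilts: np.ndarray) -> np.ndarray:
    X = np.column_stack(
        [np.ones(len(cells)), np.log(cells["sigma_c"].to_numpy(dtype=float))]
        + [
            (cells["tau_c"].to_numpy(dtype=float) == t).astype(float)
            for t in tilts[1:]
        ]
    )
    beta, *_ = np.linalg.lstsq(X, cells["w_d"].to_numpy(dtype=float))
    return beta


def fit_trend(
    wmap: WeightMap,
    n_boot: int = 1000,
    seed: int = 0,
    phase: str = "pre",
) -> TrendFit:
    """Log-slant trend of the disparity weight, bootstrapped over subjects.

    Fits ``w_d ~ 1 + ln(sigma_c) + C(tau_c)`` on the per-subject cell
    means of one phase.  Confidence intervals come from resampling
    subjects with replacement; deterministic under ``seed``.
    """
    cells = wmap.per_subject.loc[wmap.per_subject["phase"] == phase]
    if cells.empty:
        raise ValueError(f"no cells for phase {phase!r}")
    tilts = np.sort(cells["tau_c"].unique())
    for t in tilts:
        if cells.loc[cells["tau_c"] == t, "sigma_c"].nunique() < 2:
            raise ValueError("need >= 2 slant levels per tilt for a trend fit")
    beta = _ols_trend(cells, tilts)
    subjects = np.sort(cells["subject_id"].unique())
    rng = np.random.default_rng(seed)
    by_subj = {s: g for s, g in cells.groupby("subject_id")}
    boot = np.empty(n_boot)
    for i in range(n_boot):
        draw = rng.choice(subjects, size=len(subjects), replace=True)
        sample = pd.concat([by_subj[s] for s in draw], ignore_index=True)
        boot[i] = _ols_trend(sample, tilts)[1]
    ci = tuple(np.percentile(boot, [2.5, 97.5]))
    return TrendFit(
        slope=float(beta[1]),
        intercept=float(beta[0]),
        tilt_offsets={float(t): float(b) for t, b in zip(tilts[1:], beta[2:])},
        slope_se=float(np.std(boot, ddof=1)),
        slope_ci=(float(ci[0]), float(ci[1])),
        n_boot=n_boot,
        boot_slopes=boot,
    )


@dataclass(frozen=True)
class PrePostResult:
    """Cell-wise post-minus-pre comparison for one trial table.

    ``table`` has one row per cell with the mean per-subject difference,
    the raw sign-flip permutation p-value and the max-T family-wise
    adjusted p-value (family = the 3 x 3 slant-tilt grid of the cell's
    discrepancy condition).  ``significant`` uses adjusted p < alpha.
    """

    table: pd.DataFrame
    n_perm: int
    alpha: float = 0.05

    def significance_matrix(
        self, delta_sigma: float, delta_tau: float
    ) -> pd.DataFrame:
        sub = self.table.loc[
            (self.table["delta_sigma"] == delta_sigma)
            & (self.table["delta_tau"] == delta_tau)
        ]
        return sub.pivot(index="sigma_c", columns="tau_c", values="significant")


def _tstats(diffs: np.ndarray) -> np.ndarray:
    """Paired t statistics per column; 0/0 cells map to 0."""
    n = diffs.shape[0]
    m = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = m / (sd / np.sqrt(n))
        t = np.where(sd > 0, t, np.where(np.abs(m) > 0, np.sign(m) * np.inf, 0.0))
    return t


def pre_post_test(
    wmap: WeightMap, n_perm: int = 10000, seed: int = 0, alpha: float = 0.05
) -> PrePostResult:
    """Paired sign-flip permutation test of post-minus-pre w_d per cell.

    For each discrepancy condition, per-subject cell differences (post
    mean minus pre mean) are sign-flipped ``n_perm`` times; the raw
    p-value of a cell compares its |t| with the flipped distribution,
    and the max-T adjusted p-value compares it with the distribution of
    the maximum |t| over the condition's cells, controlling family-wise
    error without assuming independence across cells.
    """
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a very coarse p-value resolution")
    ps = wmap.per_subject
    wide = ps.pivot_table(
        index="subject_id", columns=CELL_KEYS + ["phase"], values="w_d"
    )
    rng = np.random.default_rng(seed)
    rows = []
    for (dsig, dtau), _ in ps.groupby(["delta_sigma", "delta_tau"]):
        cells = sorted(
            {
                (c[2], c[3])
                for c in wide.columns
                if c[0] == dsig and c[1] == dtau
            }
        )
        diffs = np.column_stack(
            [
                (
                    wide[(dsig, dtau, sc, tc, "post")]
                    - wide[(dsig, dtau, sc, tc, "pre")]
                ).to_numpy(dtype=float)
                for sc, tc in cells
            ]
        )
        if np.isnan(diffs).any():
            raise ValueError("both phases are required for every subject/cell")
        n_subj, n_cells = diffs.shape
        t_obs = _tstats(diffs)
        signs = rng.choice([-1.0, 1.0], size=(n_perm, n_subj))
        m_perm = signs @ diffs / n_subj  # (n_perm, n_cells)
        s2 = np.sum(diffs**2, axis=0)  # invariant under sign flips
        var = (s2 - n_subj * m_perm**2) / (n_subj - 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t_perm = m_perm / np.sqrt(var / n_subj)
            t_perm = np.where(
                var > 0,
                t_perm,
                np.where(np.abs(m_perm) > 0, np.sign(m_perm) * np.inf, 0.0),
            )
        abs_obs = np.abs(t_obs)
        p_raw = (1.0 + np.sum(np.abs(t_perm) >= abs_obs, axis=0)) / (n_perm + 1.0)
        max_t = np.max(np.abs(t_perm), axis=1)
        p_adj = (1.0 + np.sum(max_t[:, None] >= abs_obs, axis=0)) / (n_perm + 1.0)
        for j, (sc, tc) in enumerate(cells):
            rows.append(
                {
                    "delta_sigma": dsig,
                    "delta_tau": dtau,
                    "sigma_c": sc,
                    "tau_c": tc,
                    "mean_diff": float(diffs[:, j].mean()),
                    "t": float(t_obs[j]),
                    "p_raw": float(p_raw[j]),
                    "p_maxT": float(p_adj[j]),
                    "significant": bool(p_adj[j] < alpha),
                }
            )
    return PrePostResult(table=pd.DataFrame(rows), n_perm=n_perm, alpha=alpha)
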