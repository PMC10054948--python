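"""qPCR perturbation-timing analysis: ΔΔCt relative expression, loess
trajectory fits, time to half-maximal response, and slope differentials.

Relative expression is 2**(-ΔΔCt) with ΔCt = Ct(target) - Ct(reference) and
the ΔΔCt baseline taken from the control condition at 0 h, so every curve is
expressed relative to the untreated control. Trajectories are smoothed with
a local quadratic (tricube-weighted) regression on a 0.1 h grid spanning the
observed times; the time to half max is the first grid time at which the
fitted curve reaches half of its maximum fitted value — no baseline
subtraction, matching the convention of taking half of the maximum at any
timepoint (a baseline-subtracted variant is available behind a flag).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

GRID_STEP = 0.1

CT_COLUMNS = ("condition", "replicate", "hours", "gene", "ct")


def read_ct_table(path) -> pd.DataFrame:
    ct = pd.read_csv(path, sep="\t")
    missing = set(CT_COLUMNS) - set(ct.columns)
    if missing:
        raise ValueError(f"{path}: Ct table missing columns {sorted(missing)}")
    return ct


def relative_expression(
    ct_table: pd.DataFrame,
    reference_gene: str,
    control_condition: str,
    target_gene: str | None = None,
) -> pd.DataFrame:
    """ΔΔCt fold change per (condition, replicate, timepoint).

    The baseline ΔCt is the control condition's mean ΔCt at 0 h (across its
    replicates), so control expression at 0 h averages to 1.
    """
    ct = ct_table.copy()
    genes = set(ct["gene"].unique())
    if reference_gene not in genes:
        raise ValueError(f"reference gene {reference_gene!r} absent from Ct table")
    if target_gene is None:
        targets = sorted(genes - {reference_gene})
        if len(targets) != 1:
            raise ValueError(f"specify target_gene; candidates: {targets}")
        target_gene = targets[0]

    ref = ct[ct["gene"] == reference_gene].set_index(
        ["condition", "replicate", "hours"]
    )["ct"]
    tgt = ct[ct["gene"] == target_gene].set_index(
        ["condition", "replicate", "hours"]
    )["ct"]
    missing_ref = tgt.index.difference(ref.index)
    if len(missing_ref):
        cond, rep, hrs = missing_ref[0]
        raise ValueError(
            f"missing reference Ct for condition={cond!r}, replicate={rep}, "
            f"hours={hrs}"
        )
    dct = tgt - ref.reindex(tgt.index)

    base_mask = (dct.index.get_level_values("condition") == control_condition) & (
        dct.index.get_level_values("hours") == 0
    )
    if not base_mask.any():
        raise ValueError(
            f"control condition {control_condition!r} has no 0 h measurements"
        )
    baseline = dct[base_mask].mean()
    out = dct.reset_index()
    out["rel_expr"] = 2.0 ** (-(dct.to_numpy() - baseline))
    out["gene"] = target_gene
    return out[["condition", "replicate", "hours", "gene", "rel_expr"]]


# ---------------------------------------------------------------------------
# loess
# ---------------------------------------------------------------------------

def _loess_fit(
    x: np.ndarray, y: np.ndarray, grid: np.ndarray, span: float, degree: int
) -> np.ndarray:
    """Local polynomial regression with tricube weights (R loess-style)."""
    n = len(x)
    k = max(degree + 1, int(np.ceil(span * n)))
    k = min(k, n)
    fitted = np.empty(len(grid))
    for gi, x0 in enumerate(grid):
        d = np.abs(x - x0)
        dmax = np.sort(d)[k - 1]
        if dmax == 0:
            fitted[gi] = y[d == 0].mean()
            continue
        w = np.clip(1.0 - (d / dmax) ** 3, 0.0, None) ** 3
        use = w > 0
        sw = np.sqrt(w[use])
        n_distinct = len(np.unique(x[use]))
        if n_distinct < 1:
            raise np.linalg.LinAlgError("empty local neighborhood")
        # degrade the local degree where the window cannot support it
        # (points at exactly dmax get zero weight; R rescues these grid
        # points with a pseudoinverse, a local linear fit is saner)
        for deg in range(min(degree, n_distinct - 1), -1, -1):
            V = np.vander(x[use] - x0, deg + 1, increasing=True)
            coef, _, rank, _ = np.linalg.lstsq(V * sw[:, None], y[use] * sw,
                                               rcond=None)
            if rank == deg + 1:
                fitted[gi] = coef[0]
                break
        else:  # pragma: no cover - unreachable, deg=0 always has rank 1
            raise np.linalg.LinAlgError("rank-deficient local fit")
    return fitted


@dataclass
class TrajectoryFit:
    """A loess-smoothed relative-expression trajectory on a fine time grid."""

    times: np.ndarray
    fitted: np.ndarray
    x: np.ndarray
    y: np.ndarray
    span: float
    condition: str | None = None

    @property
    def step(self) -> float:
        return float(self.times[1] - self.times[0]) if len(self.times) > 1 else GRID_STEP


def fit_trajectory(
    points: pd.DataFrame | tuple[np.ndarray, np.ndarray],
    span: float = 0.75,
    degree: int = 2,
    step: float = GRID_STEP,
    condition: str | None = None,
) -> TrajectoryFit:
    """Loess-smooth (hours, rel_expr) points onto a ``step``-hour grid.

    Replicates enter as separate points. The grid covers the observed time
    range only. A singular local fit is retried once with span widened to
    1.0, then raised.
    """
    if isinstance(points, pd.DataFrame):
        x = points["hours"].to_numpy(dtype=float)
        y = points["rel_expr"].to_numpy(dtype=float)
    else:
        x, y = (np.asarray(v, dtype=float) for v in points)
    if len(np.unique(x)) < 4:
        raise ValueError("need >= 4 distinct timepoints for a loess fit")
    order = np.argsort(x, kind="stable")
    x, y = x[order], y[order]
    grid = np.round(np.arange(x.min(), x.max() + step / 2, step), 10)
    try:
        fitted = _loess_fit(x, y, grid, span, degree)
    except np.linalg.LinAlgError:
        try:
            fitted = _loess_fit(x, y, grid, 1.0, degree)
        except np.linalg.LinAlgError as exc:
            raise RuntimeError("loess fit singular even at span=1.0") from exc
    return TrajectoryFit(times=grid, fitted=fitted, x=x, y=y, span=span,
                         condition=condition)


def half_max_time(fit: TrajectoryFit, baseline_subtract: bool = False) -> float:
    """First grid time at which the fitted curve reaches half its maximum.

    With ``baseline_subtract=True`` the threshold is instead halfway between
    the fitted 0 h value and the maximum.
    """
    m = fit.fitted.max()
    if baseline_subtract:
        threshold = fit.fitted[0] + (m - fit.fitted[0]) / 2.0
    else:
        threshold = m / 2.0
    idx = np.flatnonzero(fit.fitted >= threshold - 1e-12)
    return float(fit.times[idx[0]])


def slope_series(fit: TrajectoryFit) -> np.ndarray:
    """d(fitted)/dt on the grid (central differences)."""
    return np.gradient(fit.fitted, fit.times)


def aggregate_slopes(
    fits: list[TrajectoryFit], group_labels: list[str]
) -> pd.DataFrame:
    """Per-grid-time mean slope with 95% CI for each group (e.g. targeted
    vs control). All fits must share one grid. Groups of a single fit get a
    zero-width CI and ``ci_defined=False``.
    """
    if len(fits) != len(group_labels):
        raise ValueError("fits and group_labels must align")
    if not fits:
        raise ValueError("no fits supplied")
    times = fits[0].times
    for f in fits[1:]:
        if len(f.times) != len(times) or not np.allclose(f.times, times):
            raise ValueError("all fits must share the same time grid")
    rows = []
    z = stats.norm.ppf(0.975)
    for group in dict.fromkeys(group_labels):
        slopes = np.array(
            [slope_series(f) for f, g in zip(fits, group_labels) if g == group]
        )
        if slopes.size == 0:
            raise ValueError(f"group {group!r} is empty")
        mean = slopes.mean(axis=0)
        n = slopes.shape[0]
        half = (z * slopes.std(axis=0, ddof=1) / np.sqrt(n)) if n > 1 else np.zeros_like(mean)
        rows.append(
            pd.DataFrame(
                {
                    "group": group,
                    "hours": times,
                    "mean_slope": mean,
                    "ci_low": mean - half,
                    "ci_high": mean + half,
                    "n": n,
                    "ci_defined": n > 1,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def timing_summary(
    rel_expr: pd.DataFrame,
    span: float = 0.75,
    baseline_subtract: bool = False,
) -> tuple[pd.DataFrame, dict[str, TrajectoryFit]]:
    """Per-condition loess fit, half-max time, and max fold change."""
    rows = []
    fits: dict[str, TrajectoryFit] = {}
    for condition, sub in rel_expr.groupby("condition", sort=True):
        fit = fit_trajectory(sub, span=span, condition=str(condition))
        fits[str(condition)] = fit
        rows.append(
            {
                "condition": condition,
                "half_max_h": half_max_time(fit, baseline_subtract=baseline_subtract),
                "max_fold": float(fit.fitted.max()),
            }
        )
    return pd.DataFrame(rows), fits
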