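"""Window-size effect analysis.

Per activity, run-level AUCs are regressed on window size with an
ordinary-least-squares quadratic (uncentered, raw sample units).  The
effect size is the range (max - min) of the fitted curve over the
explored window-size interval, evaluated analytically at the endpoints
and — when the curvature is negative — the interior vertex.  An effect
size of at least 0.05 AUC flags the activity as having a relevant
window-size effect; adjusted R-squared is reported alongside as the
goodness-of-fit half of the joint criterion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from wristhar.classification import RunResult

#: Explored window-size range in samples.
DEFAULT_RANGE = (15.0, 149.0)

#: Minimum achievable AUC change counting as a relevant effect.
RELEVANCE_THRESHOLD = 0.05


@dataclass(frozen=True)
class WindowSizeFit:
    """Quadratic-regression summary for one activity."""

    activity: str
    coefficients: tuple[float, float, float]  # (intercept, linear, quadratic)
    r2: float
    adjusted_r2: float
    effect_size: float
    local_max_window: float | None
    relevant: bool
    n_points: int
    explored_range: tuple[float, float] = DEFAULT_RANGE

    def predict(self, w: np.ndarray | float) -> np.ndarray | float:
        b0, b1, b2 = self.coefficients
        return b0 + b1 * np.asarray(w, dtype=float) + b2 * np.asarray(w, dtype=float) ** 2


def _quad_extrema(
    coefficients: tuple[float, float, float], lo: float, hi: float
) -> tuple[float, float, float | None]:
    """(max, min, interior vertex or None) of a quadratic on [lo, hi]."""
    b0, b1, b2 = coefficients
    candidates = [lo, hi]
    vertex = None
    if b2 != 0.0:
        v = -b1 / (2.0 * b2)
        if lo < v < hi:
            vertex = v
            candidates.append(v)
    vals = [b0 + b1 * w + b2 * w * w for w in candidates]
    return max(vals), min(vals), vertex


def effect_size(
    fit: "WindowSizeFit | tuple[float, float, float]",
    explored_range: tuple[float, float] = DEFAULT_RANGE,
) -> float:
    """Achievable AUC change: range of the quadratic over the explored interval.

    Accepts either a :class:`WindowSizeFit` or a raw coefficient triple.
    """
    coefficients = fit.coefficients if isinstance(fit, WindowSizeFit) else fit
    hi_v, lo_v, _ = _quad_extrema(coefficients, *explored_range)
    return hi_v - lo_v


def fit_quadratic(
    points: Iterable[tuple[float, float]],
    activity: str = "",
    explored_range: tuple[float, float] = DEFAULT_RANGE,
    threshold: float = RELEVANCE_THRESHOLD,
) -> WindowSizeFit:
    """OLS fit of AUC on (w, w^2) over run-level points.

    Requires at least 3 distinct window sizes (otherwise the quadratic
    is unidentifiable).  Adjusted R-squared uses n - 3 model degrees of
    freedom; for a constant response (zero variance) both R-squared
    values are defined as 0.
    """
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (window_size, auc) pairs")
    w, auc = pts[:, 0], pts[:, 1]
    if len(np.unique(w)) < 3:
        raise ValueError("need >= 3 distinct window sizes for a quadratic fit")

    if np.ptp(auc) == 0.0:
        # constant response: zero effect, R-squared defined as 0
        return WindowSizeFit(
            activity=activity,
            coefficients=(float(auc[0]), 0.0, 0.0),
            r2=0.0,
            adjusted_r2=0.0,
            effect_size=0.0,
            local_max_window=None,
            relevant=False,
            n_points=len(auc),
            explored_range=explored_range,
        )

    # centre internally for conditioning; report raw-scale coefficients
    mu = w.mean()
    wc = w - mu
    design = np.column_stack([np.ones_like(wc), wc, wc**2])
    beta_c, *_ = np.linalg.lstsq(design, auc, rcond=None)
    c0, c1, c2 = beta_c
    b2 = c2
    b1 = c1 - 2.0 * c2 * mu
    b0 = c0 - c1 * mu + c2 * mu * mu
    coefficients = (float(b0), float(b1), float(b2))

    fitted = design @ beta_c
    ss_res = float(((auc - fitted) ** 2).sum())
    ss_tot = float(((auc - auc.mean()) ** 2).sum())
    n = len(auc)
    r2 = 1.0 - ss_res / ss_tot
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 3) if n > 3 else r2

    es = effect_size(coefficients, explored_range)
    _, _, vertex = _quad_extrema(coefficients, *explored_range)
    local_max = vertex if (coefficients[2] < 0 and vertex is not None) else None
    return WindowSizeFit(
        activity=activity,
        coefficients=coefficients,
        r2=r2,
        adjusted_r2=adj,
        effect_size=es,
        local_max_window=local_max,
        relevant=es >= threshold,
        n_points=n,
        explored_range=explored_range,
    )


def fit_runs(
    runs: Sequence[RunResult],
    explored_range: tuple[float, float] = DEFAULT_RANGE,
    threshold: float = RELEVANCE_THRESHOLD,
    aggregate: bool = False,
) -> list[WindowSizeFit]:
    """One quadratic fit per activity from run-level results.

    ``aggregate=True`` switches from run-level points to per-window-size
    mean AUCs.
    """
    by_activity: dict[str, list[tuple[float, float]]] = {}
    for r in runs:
        by_activity.setdefault(r.activity, []).append((float(r.window_size), r.auc))
    fits = []
    for activity, pts in sorted(by_activity.items()):
        if aggregate:
            df = pd.DataFrame(pts, columns=["w", "auc"])
            pts = list(df.groupby("w")["auc"].mean().items())
        fits.append(
            fit_quadratic(pts, activity=activity, explored_range=explored_range, threshold=threshold)
        )
    return fits


def classify_relevance(fits: Sequence[WindowSizeFit]) -> pd.DataFrame:
    """Tabulate fits, flagging those whose effect size crosses the threshold."""
    if not fits:
        raise ValueError("need at least one fit")
    rows = []
    for f in fits:
        b0, b1, b2 = f.coefficients
        rows.append(
            {
                "activity": f.activity,
                "b0": b0,
                "b1": b1,
                "b2": b2,
                "r2": f.r2,
                "adj_r2": f.adjusted_r2,
                "effect_size": f.effect_size,
                "local_max_window": f.local_max_window,
                "relevant": f.relevant,
            }
        )
    return pd.DataFrame(rows).sort_values("effect_size", ascending=False).reset_index(drop=True)
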