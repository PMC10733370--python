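"""Pre/post-induction response plasticity and its relation to OKR potentiation.

Two per-neuron change metrics on the response amplitude to a probe direction
(default temporo-nasal):

* plasticity index  PI = (R_post - R_pre) / (R_post + R_pre), in [-1, 1]
  for non-negative amplitudes;
* plasticity strength  dR = (R_post - R_pre) / R_pre, averaged within
  direction groups to give each population's plasticity strength.

They are linked by the identity PI = dR / (dR + 2).  Recording-level mean PI
is regressed against behavioral OKR potentiation two ways: ordinary least
squares (the Gaussian maximum-likelihood line) and the minimum-vertical-
distance line (sum of absolute vertical residuals, Nelder-Mead).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .errors import InvalidParameterError, UndefinedMetricError
from .synthetic import GROUP_DIRECTIONS

DEFAULT_PROBE_DIRECTION = 0.0  # temporo-nasal


@dataclass(frozen=True)
class PlasticityRecord:
    neuron_id: int
    group: str
    r_pre: float
    r_post: float

    @property
    def pi(self) -> float:
        return plasticity_index(self.r_pre, self.r_post)

    @property
    def delta_r(self) -> float:
        return delta_r(self.r_pre, self.r_post)


@dataclass(frozen=True)
class FitResult:
    slope: float
    intercept: float
    r_squared: float
    method: str


def plasticity_index(r_pre, r_post):
    """PI = (R_post - R_pre)/(R_post + R_pre)."""
    r_pre = np.asarray(r_pre, dtype=float)
    r_post = np.asarray(r_post, dtype=float)
    denom = r_pre + r_post
    if np.any(denom == 0):
        raise UndefinedMetricError("R_pre + R_post = 0; plasticity index undefined")
    out = (r_post - r_pre) / denom
    return float(out) if out.ndim == 0 else out


def delta_r(r_pre, r_post):
    """Plasticity strength dR = (R_post - R_pre)/R_pre."""
    r_pre = np.asarray(r_pre, dtype=float)
    r_post = np.asarray(r_post, dtype=float)
    if np.any(r_pre <= 0):
        raise InvalidParameterError("R_pre must be positive for delta_r")
    out = (r_post - r_pre) / r_pre
    return float(out) if out.ndim == 0 else out


def classify_group(sampled_pref_deg: float) -> str:
    """Direction group of a neuron from its sampled preferred direction."""
    for group, direction in GROUP_DIRECTIONS.items():
        if abs((sampled_pref_deg - direction + 180.0) % 360.0 - 180.0) <= 45.0 - 1e-9:
            return group
    # exactly on a 45-degree boundary: snap to the nearest canonical direction
    dirs = np.array(list(GROUP_DIRECTIONS.values()))
    names = list(GROUP_DIRECTIONS)
    return names[int(np.argmin(np.abs((dirs - sampled_pref_deg + 180) % 360 - 180)))]


def build_plasticity_records(
    pre_metrics: pd.DataFrame,
    post_metrics: pd.DataFrame,
    probe_direction_deg: float = DEFAULT_PROBE_DIRECTION,
    *,
    require_pre_responsive: bool = True,
) -> list[PlasticityRecord]:
    """Pair the per-neuron metric tables of two sessions into plasticity
    records at the probe direction.

    Neurons are matched on ``neuron_id``; only neurons classified responsive
    in the *pre* session enter (pre-session gating avoids
    regression-to-the-mean artifacts), and grouping uses the pre-session
    sampled preferred direction.
    """
    col = f"amp_{probe_direction_deg:g}"
    if col not in pre_metrics or col not in post_metrics:
        raise InvalidParameterError(f"probe direction {probe_direction_deg} not sampled")
    merged = pre_metrics.merge(
        post_metrics[["neuron_id", col]], on="neuron_id", suffixes=("_pre", "_post")
    )
    if require_pre_responsive:
        merged = merged[merged["responsive"].fillna(False)]
    records = []
    for _, row in merged.iterrows():
        if np.isnan(row["sampled_pref_deg"]):
            continue
        records.append(
            PlasticityRecord(
                neuron_id=int(row["neuron_id"]),
                group=classify_group(row["sampled_pref_deg"]),
                r_pre=float(row[f"{col}_pre"]),
                r_post=float(row[f"{col}_post"]),
            )
        )
    return records


def group_plasticity_strength(records) -> pd.DataFrame:
    """Mean +/- SEM of dR per direction group.

    Groups with no records are absent from the table (missing, not zero).
    Records with non-positive R_pre are excluded (dR undefined).
    """
    rows = []
    by_group: dict[str, list[float]] = {}
    for rec in records:
        if rec.r_pre > 0:
            by_group.setdefault(rec.group, []).append(rec.delta_r)
    for group, vals in by_group.items():
        arr = np.asarray(vals)
        sem = arr.std(ddof=1) / np.sqrt(len(arr)) if len(arr) > 1 else np.nan
        rows.append(
            {"group": group, "mean_delta_r": arr.mean(), "sem": sem, "n": len(arr)}
        )
    return pd.DataFrame(rows, columns=["group", "mean_delta_r", "sem", "n"])


def fit_potentiation_vs_plasticity(
    x, y, method: str = "gaussian_mle"
) -> FitResult:
    """Line through per-recording (mean PI, OKR potentiation) points.

    ``gaussian_mle``: closed-form least squares (the ML line under Gaussian
    residuals).  ``min_vertical_distance``: minimizes the summed absolute
    vertical distances with Nelder-Mead, started from the least-squares
    line.  R^2 = 1 - SS_res/SS_tot under the fitted line in both cases.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise InvalidParameterError("need at least 3 points")
    if np.var(x) == 0:
        raise InvalidParameterError("degenerate x (zero variance); no fit")
    slope_ls = float(np.cov(x, y, bias=True)[0, 1] / np.var(x))
    intercept_ls = float(y.mean() - slope_ls * x.mean())
    if method == "gaussian_mle":
        slope, intercept = slope_ls, intercept_ls
    elif method == "min_vertical_distance":
        res = optimize.minimize(
            lambda p: np.abs(y - (p[0] * x + p[1])).sum(),
            x0=[slope_ls, intercept_ls],
            method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-10, "maxiter": 10000},
        )
        slope, intercept = float(res.x[0]), float(res.x[1])
    else:
        raise InvalidParameterError(f"unknown regression method {method!r}")
    ss_res = float(np.sum((y - (slope * x + intercept)) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return FitResult(slope=slope, intercept=intercept, r_squared=r2, method=method)
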