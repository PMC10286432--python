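"""Design-weighted area-level summaries of individual survey records.

Individual binary outcomes with sampling weights are reduced, per area, to a
Horvitz-Thompson (Hajek ratio) prevalence estimate, a with-replacement
linearized design variance, and the empirical-logit Gaussian approximation

    y_L | p  ~  N( logit(p),  var(p_hat) / (p_hat^2 (1 - p_hat)^2) )

which carries the survey design into the area-level spatial model.  Areas
with a degenerate direct estimate (p_hat in {0, 1}, zero design variance, or
too few PSUs to estimate one) are either continuity-corrected or dropped to
"unsampled" status.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ht_prevalence",
    "design_variance",
    "empirical_logit",
    "adjust_degenerate",
    "DegenerateEstimateError",
    "summarize",
    "read_records_csv",
    "write_summary_csv",
    "read_summary_csv",
]

STATUS_OBSERVED = "observed"
STATUS_ADJUSTED = "degenerate_adjusted"
STATUS_UNSAMPLED = "unsampled"


class DegenerateEstimateError(ValueError):
    """Direct estimate unusable as-is; apply ``adjust_degenerate`` first."""


def _check_weights(weights, unit_ids=None):
    weights = np.asarray(weights, dtype=float)
    bad = np.flatnonzero(~(weights > 0))
    if bad.size:
        which = unit_ids[bad[0]] if unit_ids is not None else f"record {bad[0]}"
        raise ValueError(f"nonpositive sampling weight for unit {which!r}")
    return weights


def ht_prevalence(outcomes, weights, unit_ids=None) -> tuple[float, int]:
    """Design-weighted prevalence for one area: sum(y*s) / sum(s).

    Returns ``(p_hat, n)``.  Reduces to the sample mean under equal weights
    and is invariant to rescaling all weights by a positive constant.
    """
    y = np.asarray(outcomes, dtype=float)
    if y.size == 0:
        raise ValueError("no records for area")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("outcomes must be binary 0/1")
    s = _check_weights(weights, unit_ids)
    return float(np.sum(y * s) / np.sum(s)), int(y.size)


def design_variance(outcomes, weights, psu_ids=None) -> float:
    """With-replacement linearized variance of the weighted ratio estimator.

    With PSU labels, linearized residuals are totalled per PSU before the
    between-PSU sum of squares (first-stage with-replacement approximation);
    without them each record is treated as its own sampling unit.  Raises
    ``DegenerateEstimateError`` with a single PSU (or record).
    """
    y = np.asarray(outcomes, dtype=float)
    s = _check_weights(weights)
    p_hat = np.sum(y * s) / np.sum(s)
    z = s * (y - p_hat) / np.sum(s)
    if psu_ids is not None:
        z = pd.Series(z).groupby(np.asarray(psu_ids)).sum().to_numpy()
    m = z.size
    if m < 2:
        kind = "PSU" if psu_ids is not None else "record"
        raise DegenerateEstimateError(
            f"design variance undefined with a single {kind}"
        )
    return float(m / (m - 1) * np.sum(z**2))


def empirical_logit(p_hat: float, var_p: float) -> tuple[float, float]:
    """Empirical-logit transform and its delta-method design variance."""
    if not (0.0 < p_hat < 1.0):
        raise DegenerateEstimateError(
            f"p_hat={p_hat} on the boundary; apply adjust_degenerate first"
        )
    var_logit = var_p / (p_hat**2 * (1.0 - p_hat) ** 2)
    if not var_logit > 0.0:
        raise DegenerateEstimateError(
            "var_logit must be positive; zero design variance needs adjustment"
        )
    return float(np.log(p_hat / (1.0 - p_hat))), float(var_logit)


def adjust_degenerate(outcomes, weights, rule: str = "continuity") -> tuple[float, float] | None:
    """Re-estimate a degenerate area.

    ``continuity`` (default) adds 0.5 pseudo-successes and 0.5
    pseudo-failures at the average weight before re-applying the weighted
    ratio, and floors the design variance at the binomial variance
    ``p(1-p)/n`` of the corrected estimate.  ``exclude`` returns ``None``:
    the caller should mark the area unsampled.
    """
    if rule == "exclude":
        return None
    if rule != "continuity":
        raise ValueError(f"unknown degeneracy rule {rule!r}")
    y = np.asarray(outcomes, dtype=float)
    s = _check_weights(weights)
    wbar = float(np.mean(s))
    p = (np.sum(y * s) + 0.5 * wbar) / (np.sum(s) + wbar)
    n = y.size
    floor = p * (1.0 - p) / n
    try:
        var = design_variance(y, s)
    except DegenerateEstimateError:
        var = 0.0
    return float(p), float(max(var, floor))


@dataclass(frozen=True)
class ColumnMap:
    """Column names of a record table."""

    unit: str = "unit_id"
    area: str = "area_id"
    outcome: str = "outcome"
    weight: str = "weight"
    psu: str | None = "psu_id"


def read_records_csv(path, columns: ColumnMap = ColumnMap()) -> pd.DataFrame:
    df = pd.read_csv(path)
    needed = [columns.unit, columns.area, columns.outcome, columns.weight]
    if columns.psu is not None and columns.psu in df.columns:
        needed.append(columns.psu)
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"records file missing columns {missing}")
    return df[needed]


def summarize(
    records: pd.DataFrame,
    area_ids=None,
    columns: ColumnMap = ColumnMap(),
    degeneracy_rule: str = "continuity",
) -> pd.DataFrame:
    """Per-area DistrictSummary table from individual records.

    Returns a DataFrame indexed by area id with columns ``n``, ``p_hat``,
    ``var_p``, ``y_logit``, ``var_logit`` and ``status``.  Areas listed in
    ``area_ids`` but absent from the records come out as ``unsampled`` with
    NaN summaries, so the spatial model can predict them.
    """
    psu_col = columns.psu if (columns.psu and columns.psu in records.columns) else None
    rows = {}
    for area, grp in records.groupby(columns.area, sort=False):
        y = grp[columns.outcome].to_numpy(dtype=float)
        s = grp[columns.weight].to_numpy(dtype=float)
        units = grp[columns.unit].to_numpy()
        psu = grp[psu_col].to_numpy() if psu_col else None
        p_hat, n = ht_prevalence(y, s, unit_ids=units)
        status = STATUS_OBSERVED
        try:
            var_p = design_variance(y, s, psu_ids=psu)
        except DegenerateEstimateError:
            var_p = np.nan
        # exact cancellation of PSU residuals can yield a spuriously zero
        # design variance; treat anything below 1e-12 as degenerate too
        degenerate = not (0.0 < p_hat < 1.0) or not (var_p > 1e-12)
        if degenerate:
            adj = adjust_degenerate(y, s, rule=degeneracy_rule)
            if adj is None:
                rows[area] = (n, p_hat, var_p, np.nan, np.nan, STATUS_UNSAMPLED)
                continue
            p_hat, var_p = adj
            status = STATUS_ADJUSTED
        y_logit, var_logit = empirical_logit(p_hat, var_p)
        rows[area] = (n, p_hat, var_p, y_logit, var_logit, status)

    if area_ids is None:
        area_ids = list(rows)
    data = []
    for area in area_ids:
        if area in rows:
            data.append((area, *rows[area]))
        else:
            data.append((area, 0, np.nan, np.nan, np.nan, np.nan, STATUS_UNSAMPLED))
    extra = [a for a in rows if a not in set(area_ids)]
    if extra:
        raise ValueError(f"records reference areas not in area_ids: {extra!r}")
    out = pd.DataFrame(
        data, columns=["area_id", "n", "p_hat", "var_p", "y_logit", "var_logit", "status"]
    ).set_index("area_id")
    return out


def write_summary_csv(summaries: pd.DataFrame, path) -> None:
    summaries.to_csv(path, index_label="area_id")


def read_summary_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path).set_index("area_id")
    needed = {"n", "p_hat", "var_p", "y_logit", "var_logit", "status"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"summary file missing columns {sorted(missing)}")
    return df
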