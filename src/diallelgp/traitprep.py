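"""Trait engineering: raw field measurements to analysis-ready phenotypes.

Dry-matter content is derived from under-water weighing with the empirical
specific-gravity calibration ``DM% = 214 * (Wa / (Wa - Ww) - 0.988)``;
ordinal 1-9 grades with a sparsely used low end are pooled onto a 1-6 scale;
tuber length/diameter batches are cleaned with a two-tailed Dixon Q test
before the length/width ratio is formed; and per-trait descriptive statistics
(range, mean, SE, variance, CV) summarise the resulting trait table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "InvalidMeasurementError",
    "OutlierReport",
    "dry_matter_percent",
    "recode_grade_scale",
    "dixon_q_critical",
    "dixon_q_filter",
    "length_width_ratio",
    "descriptive_stats",
    "flag_extreme_values",
]


class InvalidMeasurementError(ValueError):
    """A raw measurement violates its physical constraints."""


# Two-tailed Dixon Q (r10) critical values, n = 3..30, from the standard
# tables at the 90/95/99% confidence levels.  Larger batches use a least
# squares extrapolation Qcrit ~ a + b/sqrt(n) fitted to these points.
_Q_TABLE = {
    0.90: [0.941, 0.765, 0.642, 0.560, 0.507, 0.468, 0.437, 0.412, 0.392,
           0.376, 0.361, 0.349, 0.338, 0.329, 0.320, 0.313, 0.306, 0.300,
           0.295, 0.290, 0.285, 0.281, 0.277, 0.273, 0.269, 0.266, 0.263,
           0.260],
    0.95: [0.970, 0.829, 0.710, 0.625, 0.568, 0.526, 0.493, 0.466, 0.444,
           0.426, 0.410, 0.396, 0.384, 0.374, 0.365, 0.356, 0.349, 0.342,
           0.337, 0.331, 0.326, 0.321, 0.317, 0.312, 0.308, 0.305, 0.301,
           0.298],
    0.99: [0.994, 0.926, 0.821, 0.740, 0.680, 0.634, 0.598, 0.568, 0.542,
           0.522, 0.503, 0.488, 0.475, 0.463, 0.452, 0.442, 0.433, 0.425,
           0.418, 0.411, 0.404, 0.399, 0.393, 0.388, 0.384, 0.380, 0.376,
           0.372],
}

_MAX_BATCH = 200


@dataclass
class OutlierReport:
    """Record of a Dixon-Q cleaned batch."""

    batch_id: str
    n: int
    confidence: float
    qcrit: float
    removed: list[tuple[float, float]] = field(default_factory=list)  # (value, Q)
    warning: str | None = None


def dry_matter_percent(weight_air: float, weight_water: float) -> float:
    """Dry-matter content (%) from in-air and under-water tuber weights (kg).

    Uses the empirical linear calibration against specific gravity:
    ``DM% = 214 * (Wa / (Wa - Ww) - 0.988)``.

    Raises
    ------
    InvalidMeasurementError
        If ``weight_air <= weight_water`` (non-positive buoyancy denominator)
        or ``weight_water < 0``.
    """
    wa = float(weight_air)
    ww = float(weight_water)
    if ww < 0 or wa <= ww:
        raise InvalidMeasurementError(
            f"need weight_air > weight_water >= 0, got ({wa}, {ww})"
        )
    return 214.0 * (wa / (wa - ww) - 0.988)


def recode_grade_scale(values, pool_threshold: int = 4):
    """Recode ordinal 1-9 grades to 1-6 by pooling all grades <= threshold.

    Grades up to ``pool_threshold`` map to 1; grades above shift down so
    that the maximum grade 9 maps to 6 (``v -> max(v - pool_threshold + 1, 1)``).
    The map is monotone; with ``pool_threshold=1`` it is the identity, so a
    second pass over already-recoded 1-6 values leaves them unchanged.
    """
    arr = np.asarray(values)
    scalar = arr.ndim == 0
    arr = np.atleast_1d(arr).astype(float)
    if np.any((arr < 1) | (arr > 9)) or np.any(arr != np.round(arr)):
        raise ValueError("grades must be integers within the declared 1-9 scale")
    out = np.maximum(arr - (pool_threshold - 1), 1).astype(int)
    return int(out[0]) if scalar else out


def dixon_q_critical(n: int, confidence: float = 0.95) -> float:
    """Two-tailed Dixon Q critical value for a batch of size ``n``.

    Tabulated for n <= 30; for 30 < n <= 200 extrapolated by the least
    squares fit ``Qcrit ~ a + b / sqrt(n)`` to the tabulated points.
    """
    if confidence not in _Q_TABLE:
        raise ValueError(f"confidence must be one of {sorted(_Q_TABLE)}")
    if not 3 <= n <= _MAX_BATCH:
        raise ValueError(f"batch size must be in [3, {_MAX_BATCH}], got {n}")
    tab = _Q_TABLE[confidence]
    if n <= 30:
        return tab[n - 3]
    ns = np.arange(3, 31)
    a, b = np.linalg.lstsq(
        np.column_stack([np.ones_like(ns, dtype=float), 1.0 / np.sqrt(ns)]),
        np.asarray(tab),
        rcond=None,
    )[0]
    return float(a + b / np.sqrt(n))


def dixon_q_filter(batch, confidence: float = 0.95, batch_id: str = ""):
    """Iteratively remove outliers from a batch by the two-tailed Dixon Q test.

    ``Q = |suspect - nearest neighbour| / range`` for the more extreme of the
    two end points; values are removed one at a time, most extreme first,
    while Q exceeds the critical value.  Zero-range batches are returned
    unchanged, and batches with fewer than three values are returned
    unchanged with a warning on the report.

    Returns
    -------
    (kept, report) : (np.ndarray, OutlierReport)
    """
    values = np.asarray(batch, dtype=float)
    n0 = values.size
    if n0 > _MAX_BATCH:
        raise ValueError(f"batch size {n0} exceeds the supported maximum {_MAX_BATCH}")
    if n0 < 3:
        rep = OutlierReport(batch_id, n0, confidence, np.nan,
                            warning="batch smaller than 3; not tested")
        return values.copy(), rep

    kept = np.sort(values)
    report = OutlierReport(batch_id, n0, confidence,
                           dixon_q_critical(n0, confidence))
    while kept.size >= 3:
        rng = kept[-1] - kept[0]
        if rng == 0:
            break
        q_low = (kept[1] - kept[0]) / rng
        q_high = (kept[-1] - kept[-2]) / rng
        qcrit = dixon_q_critical(kept.size, confidence)
        if q_high >= q_low:
            suspect, q = kept[-1], q_high
            idx = kept.size - 1
        else:
            suspect, q = kept[0], q_low
            idx = 0
        if q > qcrit:
            report.removed.append((float(suspect), float(q)))
            kept = np.delete(kept, idx)
        else:
            break
    return kept, report


def length_width_ratio(length: float, diameter: float) -> float:
    """Tuber length over diameter (both mm, both positive)."""
    if diameter <= 0 or length <= 0:
        raise InvalidMeasurementError(
            f"length and diameter must be positive, got ({length}, {diameter})"
        )
    return float(length) / float(diameter)


def flag_extreme_values(table: pd.DataFrame, trait: str, threshold: float) -> pd.DataFrame:
    """List (without removing) observations of ``trait`` above ``threshold``.

    Extreme dry-matter records are deliberately retained in the analysis for
    dataset completeness; this helper only reports them for inspection.
    """
    sub = table[(table["trait"] == trait) & (table["value"] > threshold)]
    return sub.copy()


def descriptive_stats(table: pd.DataFrame) -> pd.DataFrame:
    """Per-trait descriptive statistics of a long-format trait table.

    Expects columns ``trait``, ``value`` and optionally ``replicate``.
    Returns one row per trait with ``range``, ``mean``, ``se``, ``variance``
    (sample variance), ``cv`` (= sqrt(variance)/mean, missing for zero mean),
    ``n_obs`` and ``n_rep``.
    """
    rows = []
    for trait, grp in table.groupby("trait", sort=True):
        v = grp["value"].dropna().to_numpy(dtype=float)
        n = v.size
        if n < 2:
            raise ValueError(f"trait {trait!r} has fewer than 2 observations")
        mean = v.mean()
        var = v.var(ddof=1)
        cv = np.sqrt(var) / mean if mean != 0 else np.nan
        n_rep = int(grp["replicate"].nunique()) if "replicate" in grp else 1
        rows.append({
            "trait": trait,
            "min": v.min(),
            "max": v.max(),
            "mean": mean,
            "se": np.sqrt(var / n),
            "variance": var,
            "cv": cv,
            "n_obs": n,
            "n_rep": n_rep,
        })
    return pd.DataFrame(rows).set_index("trait")
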