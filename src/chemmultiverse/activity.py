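"""Multi-endpoint activity aggregation: mpIC50, SD sizing, scores, promiscuity.

All activities are on the negative-log-molar (pKI / pIC50) scale, so the
potency thresholds translate as 1 uM <-> pKI 6 and 100 nM <-> pKI 7. Missing
endpoint values are excluded from means and fractions; a compound with no
data at all gets undefined (None) aggregates rather than zeros.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from chemmultiverse.dataio import ActivityMatrix

PKI_1UM = 6.0  # 1 uM on the pKI scale
PKI_100NM = 7.0  # 100 nM


@dataclass
class CategoryThresholds:
    """Per-endpoint activity categories and their integer scores.

    Defaults: active (pKI >= 6) -> 4; non-specific (4.5 <= pKI < 6) -> 3;
    inactive (pKI < 4.5) -> 2; unknown (no reported value) -> 1.
    """

    active_min: float = 6.0
    nonspecific_min: float = 4.5
    scores: dict[str, int] = field(
        default_factory=lambda: {"active": 4, "nonspecific": 3, "inactive": 2, "unknown": 1}
    )

    def __post_init__(self) -> None:
        if not self.nonspecific_min < self.active_min:
            raise ValueError("nonspecific_min must be below active_min")


@dataclass
class ActivitySummary:
    """Per-compound aggregates over all endpoints."""

    id: str
    mpic50: float | None
    sd: float | None
    sd_norm: float
    category_scores: list[int]
    aggregate_score: int
    frac_1uM: float | None
    frac_100nM: float | None


def _observed(row: np.ma.MaskedArray | Sequence[float | None]) -> np.ndarray:
    """Non-missing values of one activity row as a plain array."""
    if isinstance(row, np.ma.MaskedArray):
        return np.asarray(row.compressed(), dtype=float)
    vals = [v for v in row if v is not None and not (isinstance(v, float) and np.isnan(v))]
    return np.asarray(vals, dtype=float)


def mpic50(row) -> float | None:
    """Mean activity over non-missing endpoints; None when all are missing."""
    obs = _observed(row)
    return float(obs.mean()) if obs.size else None


def activity_sd(row) -> float | None:
    """Sample (n-1) standard deviation over non-missing endpoints; needs >= 2."""
    obs = _observed(row)
    return float(obs.std(ddof=1)) if obs.size >= 2 else None


def sd_sizes(sds: Sequence[float | None], min_size: float = 0.0) -> np.ndarray:
    """Map per-compound SDs to point sizes in [min_size, 1].

    Defined SDs are min-max normalized to [0, 1] then affinely mapped onto
    [min_size, 1]; undefined SDs (and every SD when the range is degenerate)
    get min_size, keeping low/no-variability compounds visible but small.
    """
    if not 0.0 <= min_size < 1.0:
        raise ValueError("min_size must be in [0, 1)")
    defined = [s for s in sds if s is not None]
    if not defined:
        raise ValueError("need at least one defined SD")
    lo, hi = min(defined), max(defined)
    out = np.full(len(sds), min_size, dtype=float)
    if hi > lo:
        for i, s in enumerate(sds):
            if s is not None:
                out[i] = min_size + (1.0 - min_size) * (s - lo) / (hi - lo)
    return out


def classify(pki: float | None, t: CategoryThresholds | None = None) -> int:
    """Category score of one endpoint value at the configured thresholds."""
    t = t or CategoryThresholds()
    if pki is None or (isinstance(pki, float) and np.isnan(pki)):
        return t.scores["unknown"]
    if pki >= t.active_min:
        return t.scores["active"]
    if pki >= t.nonspecific_min:
        return t.scores["nonspecific"]
    return t.scores["inactive"]


def aggregate_score(row, t: CategoryThresholds | None = None) -> int:
    """Sum of per-endpoint category scores; bounded by [m, 4m] for m endpoints."""
    t = t or CategoryThresholds()
    if isinstance(row, np.ma.MaskedArray):
        vals = [None if m else float(v) for v, m in zip(row.data, np.ma.getmaskarray(row))]
    else:
        vals = list(row)
    return sum(classify(v, t) for v in vals)


def promiscuity(row) -> tuple[float | None, float | None]:
    """Fractions of observed endpoints hit at 1 uM (pKI >= 6) and 100 nM (pKI >= 7).

    Both are None when the compound has no observed endpoint at all.
    """
    obs = _observed(row)
    if obs.size == 0:
        return None, None
    return (
        float((obs >= PKI_1UM).sum() / obs.size),
        float((obs >= PKI_100NM).sum() / obs.size),
    )


def summarize_activities(
    ids: Sequence[str],
    activities: ActivityMatrix,
    thresholds: CategoryThresholds | None = None,
    min_size: float = 0.1,
) -> pd.DataFrame:
    """Per-compound summary table: mpic50, sd, sd_norm, scores, promiscuity.

    Wide per-endpoint score columns (``score_<endpoint>``) follow the scalar
    aggregates. With zero endpoints the aggregates are undefined and every
    point gets ``min_size``.
    """
    thresholds = thresholds or CategoryThresholds()
    n = activities.n
    if len(ids) != n:
        raise ValueError("ids and activity rows misaligned")

    rows = []
    sds: list[float | None] = []
    for i in range(n):
        row = activities.row(i)
        sd = activity_sd(row)
        sds.append(sd)
        frac1, frac01 = promiscuity(row)
        cat = [
            classify(None if activities.missing_mask[i, j] else float(activities.values[i, j]),
                     thresholds)
            for j in range(activities.m)
        ]
        rows.append(
            {
                "id": ids[i],
                "mpic50": mpic50(row),
                "sd": sd,
                "aggregate_score": sum(cat),
                "frac_1uM": frac1,
                "frac_100nM": frac01,
                **{f"score_{name}": cat[j] for j, name in enumerate(activities.endpoint_names)},
            }
        )

    df = pd.DataFrame(rows)
    if any(s is not None for s in sds):
        df.insert(3, "sd_norm", sd_sizes(sds, min_size))
    else:
        df.insert(3, "sd_norm", np.full(n, min_size))
    return df
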