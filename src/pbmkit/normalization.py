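"""Two-colour normalization of PBM slides.

The chain mirrors standard two-colour array practice: per-spot M/A statistics
(M = log2 protein/DNA, A = mean log2 intensity), loess removal of the
intensity-dependent dye bias within each slide, quantile normalization of the
inter-slide distributions, and robust aggregation of the ~20 replicate spots
per sequence into one binding value per slide.

Loess here is local *linear* regression with tricube weights over a ``span``
fraction of the points (the classical lowess smoother), delegated to
statsmodels.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from .errors import ContractError
from .io_formats import ArraySet, SpotRecord

__all__ = [
    "MAStatistic",
    "BindingValue",
    "compute_ma",
    "ma_table",
    "loess_normalize_slide",
    "quantile_normalize",
    "aggregate_replicates",
    "normalize_arrayset",
]


@dataclass(frozen=True)
class MAStatistic:
    """Per-spot M/A pair.

    M = log2(green_net / red_net): positive M means protein signal in excess
    of the DNA amount.  A = (log2 green_net + log2 red_net) / 2.
    """

    sequence_id: str
    slide_id: str
    M: float
    A: float


@dataclass(frozen=True)
class BindingValue:
    """Per-sequence binding on one slide, aggregated over replicate spots."""

    sequence_id: str
    slide_id: str
    m_value: float
    cv_red: float | None
    cv_green: float | None
    n_spots_used: int


def compute_ma(spot: SpotRecord) -> MAStatistic | None:
    """M/A statistic of one spot, or None when either net intensity is <= 0.

    Background subtraction is plain foreground minus background per channel.
    A non-positive net intensity in either channel makes the log ratio
    undefined; such spots are *missing*, not errors.
    """
    red = spot.red_fg - spot.red_bg
    green = spot.green_fg - spot.green_bg
    if red <= 0 or green <= 0:
        return None
    return MAStatistic(
        sequence_id=spot.sequence_id,
        slide_id=spot.slide_id,
        M=math.log2(green / red),
        A=0.5 * (math.log2(green) + math.log2(red)),
    )


def ma_table(spots: list[SpotRecord], drop_flagged: bool = True) -> pd.DataFrame:
    """Vectorized M/A computation for one slide's spots.

    Returns a frame with columns ``sequence_id``, ``M``, ``A``, ``red_net``,
    ``green_net``; spots with non-positive net intensity (or negative scanner
    flags, unless ``drop_flagged`` is False) carry NaN in the numeric columns.
    """
    seq_ids = np.array([s.sequence_id for s in spots])
    red = np.array([s.red_fg - s.red_bg for s in spots], dtype=float)
    green = np.array([s.green_fg - s.green_bg for s in spots], dtype=float)
    ok = (red > 0) & (green > 0)
    if drop_flagged:
        ok &= np.array([not s.is_flagged for s in spots])
    M = np.full(len(spots), np.nan)
    A = np.full(len(spots), np.nan)
    M[ok] = np.log2(green[ok] / red[ok])
    A[ok] = 0.5 * (np.log2(green[ok]) + np.log2(red[ok]))
    red_net = np.where(ok, red, np.nan)
    green_net = np.where(ok, green, np.nan)
    return pd.DataFrame(
        {
            "sequence_id": seq_ids,
            "M": M,
            "A": A,
            "red_net": red_net,
            "green_net": green_net,
        }
    )


def loess_normalize_slide(
    m: np.ndarray,
    a: np.ndarray,
    span: float = 0.3,
    iterations: int = 1,
    min_spots: int = 10,
    delta: float | None = None,
) -> np.ndarray:
    """Subtract the loess fit of M on A within one slide.

    The working assumption is that the protein/DNA log ratio is independent of
    total fluorescence, so any smooth trend of M versus A is dye bias and is
    removed: corrected M = M - fit(A).  NaN entries are passed through.

    Parameters
    ----------
    span : fraction of points in each local window (0 < span <= 1).
    iterations : robustness iterations re-weighting outliers (0 = plain fit).
    delta : x-distance within which fitted values are linearly interpolated
        rather than refitted (as in R's ``lowess``); defaults to 1% of the A
        range, which is indistinguishable from an exact fit at array scale.
        Pass 0 to refit at every point.
    """
    if not 0 < span <= 1:
        raise ContractError(f"span must be in (0, 1], got {span}")
    m = np.asarray(m, dtype=float)
    a = np.asarray(a, dtype=float)
    if m.shape != a.shape:
        raise ContractError("M and A must have equal shapes")
    mask = np.isfinite(m) & np.isfinite(a)
    if mask.sum() < min_spots:
        raise ContractError(
            f"loess needs at least {min_spots} finite spots, got {int(mask.sum())}"
        )
    if delta is None:
        delta = 0.01 * float(np.ptp(a[mask]))
    fit = _sm_lowess(
        m[mask],
        a[mask],
        frac=span,
        it=iterations,
        delta=delta,
        return_sorted=False,
    )
    out = m.copy()
    out[mask] = m[mask] - fit
    return out


def quantile_normalize(vectors: list[np.ndarray]) -> list[np.ndarray]:
    """Force identical distributions across slides by quantile normalization.

    The rank-k value of every vector is replaced by the mean of all vectors'
    rank-k values; tied entries receive the average of their tied reference
    quantiles, so the map is well defined and idempotent.
    """
    arrays = [np.asarray(v, dtype=float) for v in vectors]
    if len(arrays) < 2:
        raise ContractError("quantile normalization needs at least 2 vectors")
    n = arrays[0].size
    for v in arrays:
        if v.size != n:
            raise ContractError("all vectors must have equal length")
        if not np.isfinite(v).all():
            raise ContractError(
                "vectors must be finite; align missing values before normalizing"
            )
    reference = np.sort(np.stack(arrays), axis=1).mean(axis=0)
    out = []
    for v in arrays:
        order = np.argsort(v, kind="stable")
        q = np.empty(n)
        q[order] = reference
        # average reference quantiles within tie groups
        uniq, inverse = np.unique(v, return_inverse=True)
        sums = np.bincount(inverse, weights=q)
        counts = np.bincount(inverse)
        out.append((sums / counts)[inverse])
    return out


def aggregate_replicates(
    m: np.ndarray,
    red_net: np.ndarray,
    green_net: np.ndarray,
    sequence_id: str,
    slide_id: str,
    method: str = "median",
) -> BindingValue | None:
    """Collapse replicate spots of one sequence on one slide.

    The binding value is the median (default; robust to the occasional bad
    spot among ~20 replicates) or mean of the replicate M values.  Channel
    CVs are 100 * sample SD / mean of the net intensities; they are reported
    missing (None) with fewer than 2 usable replicates.  Returns None when no
    replicate is usable.
    """
    if method not in ("median", "mean"):
        raise ContractError(f"unknown aggregation method {method!r}")
    m = np.asarray(m, dtype=float)
    ok = np.isfinite(m)
    if not ok.any():
        return None
    m_val = float(np.median(m[ok]) if method == "median" else np.mean(m[ok]))

    def _cv(x: np.ndarray) -> float | None:
        x = np.asarray(x, dtype=float)
        x = x[np.isfinite(x)]
        if x.size < 2 or x.mean() == 0:
            return None
        return float(100.0 * x.std(ddof=1) / x.mean())

    return BindingValue(
        sequence_id=sequence_id,
        slide_id=slide_id,
        m_value=m_val,
        cv_red=_cv(red_net),
        cv_green=_cv(green_net),
        n_spots_used=int(ok.sum()),
    )


def normalize_arrayset(
    arrays: ArraySet,
    span: float = 0.3,
    iterations: int = 1,
    quantile: str = "ratio",
    aggregate: str = "median",
    max_missing_fraction: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full normalization chain on an array set.

    Steps: per-spot M/A -> loess within each slide -> quantile normalization
    across slides -> replicate aggregation.  ``quantile`` selects what is
    quantile-normalized across slides: ``"ratio"`` (per-spot M values, the
    default), ``"channel"`` (log2 net intensities per channel, after which M
    is recomputed), or ``"none"``.

    Returns
    -------
    binding : DataFrame (sequence x slide) of aggregated m_values.  Sequences
        missing on more than ``max_missing_fraction`` of slides are dropped.
    cv : long DataFrame with per-sequence per-slide channel CVs (%) and the
        replicate count used.
    """
    if quantile not in ("ratio", "channel", "none"):
        raise ContractError(f"unknown quantile mode {quantile!r}")
    arrays.validate()
    tables = []
    for slide in arrays.slides:
        tab = ma_table(slide.spots)
        tab["M"] = loess_normalize_slide(
            tab["M"].to_numpy(), tab["A"].to_numpy(), span=span, iterations=iterations
        )
        tables.append(tab)

    n_spots = {len(t) for t in tables}
    if len(n_spots) != 1:
        raise ContractError("slides differ in spot count; cannot align spot-level data")

    if quantile != "none":
        # align: only spots finite on every slide enter the quantile map
        finite = np.logical_and.reduce([t["M"].notna().to_numpy() for t in tables])
        if quantile == "ratio":
            vectors = [t.loc[finite, "M"].to_numpy() for t in tables]
            for t, v in zip(tables, quantile_normalize(vectors)):
                col = t["M"].to_numpy()
                col[finite] = v
                t["M"] = col
        else:  # per-channel, as superimposed channel distributions suggest
            for channel in ("red_net", "green_net"):
                vectors = [np.log2(t.loc[finite, channel].to_numpy()) for t in tables]
                for t, v in zip(tables, quantile_normalize(vectors)):
                    col = t[channel].to_numpy()
                    col[finite] = 2.0**v
                    t[channel] = col
            for t in tables:
                with np.errstate(invalid="ignore", divide="ignore"):
                    t["M"] = np.log2(t["green_net"] / t["red_net"])

    binding_cols: dict[str, pd.Series] = {}
    cv_rows = []
    for slide, tab in zip(arrays.slides, tables):
        values = {}
        for seq_id, grp in tab.groupby("sequence_id", sort=True):
            bv = aggregate_replicates(
                grp["M"].to_numpy(),
                grp["red_net"].to_numpy(),
                grp["green_net"].to_numpy(),
                seq_id,
                slide.slide_id,
                method=aggregate,
            )
            if bv is None:
                values[seq_id] = np.nan
                continue
            values[seq_id] = bv.m_value
            cv_rows.append(
                {
                    "sequence_id": seq_id,
                    "slide_id": slide.slide_id,
                    "group": slide.group,
                    "cv_red": bv.cv_red,
                    "cv_green": bv.cv_green,
                    "n_spots_used": bv.n_spots_used,
                }
            )
        binding_cols[slide.slide_id] = pd.Series(values)

    binding = pd.DataFrame(binding_cols)
    missing_frac = binding.isna().mean(axis=1)
    dropped = missing_frac > max_missing_fraction
    if dropped.any():
        warnings.warn(
            f"dropping {int(dropped.sum())} sequences missing on more than "
            f"{max_missing_fraction:.0%} of slides",
            stacklevel=2,
        )
        binding = binding.loc[~dropped]
    cv = pd.DataFrame(cv_rows)
    return binding, cv
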