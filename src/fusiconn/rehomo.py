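"""Regional homogeneity via Kendall's coefficient of concordance (KCC).

For each pixel, the concordance W of the time-series ranks within its 3×3
neighbourhood (k = 9 pixels) quantifies local synchrony without any seed
choice:

    W = 12 / (k² (n³ − n)) · Σᵢ (Σⱼ R_ij − k R̄)²

where R_ij is the rank of time point i in pixel j and R̄ the mean rank.  Ties
receive midranks and the statistic is applied in this uncorrected form (exact
ties are measure-zero for continuous CBV data); this is a documented
divergence from the tie-corrected Kendall's W.  Maps are z-scored at the
animal level over the four per-animal maps (baseline / 10 min ×
VEH+KET / NTX+KET) and segmented into ROI means for group statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .preprocess import ROI_LABELS, ImageSeries, select_interval

__all__ = ["KccMap", "kcc", "kcc_map", "zscore_kcc", "segment_kcc"]


@dataclass
class KccMap:
    """Pixel-wise KCC over an interval; border/out-of-mask pixels are NaN and
    marked in ``defined`` (flagged, never zero-filled)."""

    kcc: np.ndarray
    defined: np.ndarray
    interval: tuple[float, float]
    neighborhood: int = 3
    zkcc: np.ndarray | None = None
    meta: dict = field(default_factory=dict)


def kcc(signals: np.ndarray) -> float:
    """Kendall's W of k time series of n points (k ≥ 2, n ≥ 3), in [0, 1].

    Ranks are computed within each series (midranks on ties); a constant
    series raises, since its ranks carry no ordering information.
    """
    x = np.asarray(signals, dtype=float)
    if x.ndim != 2:
        raise ValueError("signals must be k×n")
    k, n = x.shape
    if k < 2:
        raise ValueError("need k ≥ 2 series")
    if n < 3:
        raise ValueError("need n ≥ 3 time points")
    if np.any(x.std(axis=1) == 0):
        raise ValueError("constant series: ranks undefined for concordance")
    ranks = np.apply_along_axis(stats.rankdata, 1, x)   # midranks
    rank_sums = ranks.sum(axis=0)                       # Σⱼ R_ij per time point
    rbar = ranks.mean()                                 # mean rank over all j, i
    s = float(np.sum((rank_sums - k * rbar) ** 2))
    w = 12.0 * s / (k**2 * (n**3 - n))
    if w < -1e-12 or w > 1 + 1e-12:
        raise FloatingPointError(f"KCC {w} outside [0,1] beyond round-off")
    return float(min(max(w, 0.0), 1.0))


def kcc_map(
    series: ImageSeries,
    interval: tuple[float, float],
    neighborhood: int = 3,
    brain_mask: np.ndarray | None = None,
) -> KccMap:
    """Pixel-wise KCC of each pixel with its (neighborhood² − 1) neighbours.

    Computed over the valid frames of the interval.  Pixels whose full
    neighbourhood is not inside the brain mask are flagged undefined, as are
    pixels with a constant series in the window.
    """
    if neighborhood % 2 == 0 or neighborhood < 1:
        raise ValueError("neighborhood must be odd and ≥ 1")
    sub = select_interval(series, *interval)
    data = sub.data[:, :, sub.valid]
    n = data.shape[2]
    if n < 3:
        raise ValueError(f"interval {interval} has {n} valid frames; need ≥ 3")
    rows, cols = data.shape[:2]
    mask = (
        np.asarray(brain_mask, dtype=bool)
        if brain_mask is not None
        else (series.brain_mask if series.brain_mask is not None
              else np.ones((rows, cols), dtype=bool))
    )
    nonconstant = data.std(axis=2) > 0
    usable = mask & nonconstant

    # rank each pixel series once, then aggregate rank sums over the window
    # with a uniform filter — identical to running the scalar statistic per
    # neighbourhood, but vectorised over the grid
    ranks = np.empty_like(data)
    flat = data.reshape(-1, n)
    out = ranks.reshape(-1, n)
    for idx in range(flat.shape[0]):
        out[idx] = stats.rankdata(flat[idx])
    k = neighborhood * neighborhood
    rank_sums = ndimage.uniform_filter(
        ranks, size=(neighborhood, neighborhood, 1), mode="constant"
    ) * k
    rbar = (n + 1) / 2.0  # midranks: every series averages to (n+1)/2
    s = np.sum((rank_sums - k * rbar) ** 2, axis=2)
    w = 12.0 * s / (k**2 * (n**3 - n))

    # defined where the whole neighbourhood is usable
    full = ndimage.uniform_filter(
        usable.astype(float), size=neighborhood, mode="constant"
    ) > 1.0 - 0.5 / k
    w = np.where(full, np.clip(w, 0.0, 1.0), np.nan)
    return KccMap(
        kcc=w, defined=full, interval=interval, neighborhood=neighborhood,
        meta={},
    )


def zscore_kcc(maps: Sequence[KccMap]) -> list[KccMap]:
    """Animal-level z-scoring over the animal's 4 maps.

    Pools all defined pixels of the 4 maps (baseline/10-min × VEH+KET/NTX+KET),
    takes one mean and SD, and z-scores every map with them, so the four maps
    of an animal live on one comparable scale.  Degenerate (zero-SD) pooling is
    flagged by raising.
    """
    if len(maps) != 4:
        missing = 4 - len(maps)
        raise ValueError(
            f"animal-level z-scoring needs exactly the 4 maps "
            f"(baseline/10min × VEH+KET/NTX+KET); {missing} missing"
        )
    shapes = {m.kcc.shape for m in maps}
    if len(shapes) != 1:
        raise ValueError("the 4 maps must share one pixel grid")
    pooled = np.concatenate([m.kcc[m.defined] for m in maps])
    mean, sd = pooled.mean(), pooled.std()
    if sd <= 1e-12 * max(abs(mean), 1.0):
        raise ValueError("pooled KCC SD is zero: z-scores undefined (flagged)")
    out = []
    for m in maps:
        z = (m.kcc - mean) / sd
        out.append(KccMap(
            kcc=m.kcc, defined=m.defined, interval=m.interval,
            neighborhood=m.neighborhood, zkcc=z, meta=dict(m.meta),
        ))
    return out


def segment_kcc(
    zmaps: Sequence[KccMap],
    roi_layout: Mapping[str, np.ndarray],
    labels: Sequence[str] = ROI_LABELS,
) -> pd.DataFrame:
    """Per-ROI mean z-KCC table (subject, sex, condition, time, roi, z_kcc).

    ROIs left empty after excluding undefined pixels yield NaN rows (flagged
    missing, not zero).  Each map's ``meta`` supplies the design columns.
    """
    rows = []
    for m in zmaps:
        if m.zkcc is None:
            raise ValueError("segment_kcc expects z-scored maps (run zscore_kcc)")
        for lab in labels:
            px = np.asarray(roi_layout[lab])
            vals = m.zkcc[px[:, 0], px[:, 1]]
            ok = m.defined[px[:, 0], px[:, 1]]
            rows.append({
                "subject": m.meta.get("subject"),
                "sex": m.meta.get("sex"),
                "condition": m.meta.get("condition"),
                "time": m.meta.get("time"),
                "roi": lab,
                "z_kcc": float(vals[ok].mean()) if ok.any() else np.nan,
            })
    return pd.DataFrame(rows)
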