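"""Static ROI-pair functional connectivity over drug-anchored intervals.

One Pearson correlation matrix per interval (the 9-min baseline centred at
−5 min; 15-min windows centred at +10 and +40 min), Fisher-z transformed for
all statistics.  z — not r — is the quantity averaged and tested everywhere;
r is kept only for display, mirroring standard practice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .preprocess import ROI_LABELS, RoiTimeSeries, select_interval

__all__ = [
    "ConnMatrix",
    "fc_matrix",
    "fisher_z",
    "inverse_fisher",
    "contrast_pairs",
    "tidy_table",
    "pair_label",
]

#: Cap applied when |r| = 1 would send the Fisher transform to infinity.
Z_CAP_R = 0.999999


@dataclass
class ConnMatrix:
    """Symmetric 22×22 correlation matrix with its Fisher-z twin.

    ``undefined`` flags pairs whose correlation could not be computed
    (zero-variance signal); those entries are NaN, never silently 0.
    """

    r: np.ndarray
    z: np.ndarray
    interval: tuple[float, float]            # (center_min, width_min)
    labels: Sequence[str] = ROI_LABELS
    meta: dict = field(default_factory=dict)
    undefined: np.ndarray | None = None
    n_valid_frames: int = 0

    def __post_init__(self) -> None:
        r = np.asarray(self.r, dtype=float)
        if r.ndim != 2 or r.shape[0] != r.shape[1]:
            raise ValueError("r must be square")
        finite = np.isfinite(r)
        if not np.allclose(r[finite], np.asarray(r.T)[finite.T], atol=1e-10):
            raise ValueError("r must be symmetric")
        if np.any(np.abs(r[finite]) > 1 + 1e-10):
            raise ValueError("|r| must not exceed 1")
        if self.undefined is None:
            self.undefined = ~finite
        self.r = r


def fisher_z(r, warn_cap: bool = True):
    """Fisher transform z = atanh(r); |r| = 1 maps to ±atanh(0.999999).

    Accepts scalars or arrays; |r| > 1 raises.
    """
    r_arr = np.asarray(r, dtype=float)
    finite = np.isfinite(r_arr)
    if np.any(np.abs(r_arr[finite]) > 1 + 1e-12):
        raise ValueError("|r| must be ≤ 1 for the Fisher transform")
    capped = finite & (np.abs(r_arr) >= 1.0)
    if np.any(capped) and warn_cap:
        warnings.warn("|r| = 1 capped before Fisher transform", stacklevel=2)
    out = np.atleast_1d(np.arctanh(np.clip(r_arr, -Z_CAP_R, Z_CAP_R)))
    out[~np.atleast_1d(finite)] = np.nan
    return out.reshape(r_arr.shape) if np.ndim(r) else float(out[0])


def inverse_fisher(z):
    """Inverse transform r = tanh(z)."""
    out = np.tanh(np.asarray(z, dtype=float))
    return out if np.ndim(z) else float(out)


def fc_matrix(
    roits: RoiTimeSeries,
    interval: tuple[float, float],
    min_valid_frames: int = 30,
) -> ConnMatrix:
    """Pearson ROI-pair correlations over the valid frames of an interval.

    Invalid frames are dropped before correlating (the validity mask is global
    per frame, so pairwise deletion coincides with dropping those frames for
    every pair).  Pairs involving a zero-variance signal are flagged undefined
    and set to NaN.
    """
    center_min, width_min = interval
    sub = select_interval(roits, center_min, width_min)
    x = sub.signals[:, sub.valid]
    n = x.shape[1]
    if n < min_valid_frames:
        raise ValueError(
            f"only {n} valid frames in interval {interval}; need ≥ {min_valid_frames}"
        )
    sd = x.std(axis=1)
    degenerate = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x)
    r[degenerate, :] = np.nan
    r[:, degenerate] = np.nan
    np.fill_diagonal(r, 1.0)
    r = np.clip(r, -1.0, 1.0, out=r)
    undefined = np.zeros_like(r, dtype=bool)
    undefined[degenerate, :] = True
    undefined[:, degenerate] = True
    np.fill_diagonal(undefined, False)
    z = fisher_z(r, warn_cap=False)
    np.fill_diagonal(z, np.nan)  # diagonal z is not a statistic
    return ConnMatrix(
        r=r, z=z, interval=(center_min, width_min), labels=roits.labels,
        meta=dict(roits.meta), undefined=undefined, n_valid_frames=n,
    )


def pair_label(lab_i: str, lab_j: str, labels: Sequence[str] = ROI_LABELS) -> str:
    """Canonical unordered-pair name: later canonical label first, en-dash join
    (so the homotopic prelimbic pair reads ``PrL-R – PrL-L``)."""
    i, j = labels.index(lab_i), labels.index(lab_j)
    first, second = (lab_j, lab_i) if j > i else (lab_i, lab_j)
    return f"{first} – {second}"


def _pairs(labels: Sequence[str]):
    n = len(labels)
    for i in range(n):
        for j in range(i + 1, n):
            yield i, j


def tidy_table(matrices: Sequence[ConnMatrix], time_key: str = "time") -> pd.DataFrame:
    """Long-format table (subject, sex, condition, time, pair, r, z) over the
    231 unordered off-diagonal ROI pairs, ready for the mixed ANOVA."""
    rows = []
    for m in matrices:
        meta = m.meta
        t = meta.get(time_key, f"{m.interval[0]:g}min")
        for i, j in _pairs(m.labels):
            rows.append({
                "subject": meta.get("subject"),
                "sex": meta.get("sex"),
                "condition": meta.get("condition"),
                "time": t,
                "pair": pair_label(m.labels[i], m.labels[j], m.labels),
                "r": m.r[i, j],
                "z": m.z[i, j],
            })
    return pd.DataFrame(rows)


def contrast_pairs(
    matrices: Sequence[ConnMatrix],
    contrast: tuple[str, str, str] | None = None,
    time_key: str = "time",
) -> pd.DataFrame:
    """Tidy per-pair table, optionally reduced to per-subject Δz for a contrast.

    Without ``contrast`` this returns the long table from :func:`tidy_table`
    after validating that every subject contributes the same design cells.
    With ``contrast = (column, level_a, level_b)`` it returns one row per
    (subject, pair) with ``dz = z[level_a] − z[level_b]``, preserving
    subject-level pairing; unmatched subject sets raise, naming the asymmetry.
    """
    table = tidy_table(matrices, time_key=time_key)
    cells = table.groupby(["condition", "time"])["subject"].unique()
    subject_sets = [frozenset(s) for s in cells]
    if len(set(subject_sets)) > 1:
        detail = {idx: sorted(s) for idx, s in zip(cells.index, subject_sets)}
        raise ValueError(f"subjects not matched across design cells: {detail}")
    if contrast is None:
        return table
    col, level_a, level_b = contrast
    if col not in table.columns:
        raise ValueError(f"unknown contrast column {col!r}")
    a = table[table[col] == level_a]
    b = table[table[col] == level_b]
    if a.empty or b.empty:
        raise ValueError(f"contrast level(s) missing from column {col!r}")
    other = [c for c in ("subject", "sex", "condition", "time", "pair") if c != col]
    merged = a.merge(b, on=other, suffixes=("_a", "_b"))
    merged["dz"] = merged["z_a"] - merged["z_b"]
    return merged[other + ["dz", "z_a", "z_b"]]
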