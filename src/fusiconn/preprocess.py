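"""Pre-processing of registered fUSI cerebral-blood-volume (CBV) sessions.

A session enters this module as a pixel-grid power-Doppler time stack that is
already motion-corrected and atlas-aligned.  The operations here turn it into
filtered, censored, interval-addressable ROI and pixel time series:

* :func:`bandpass` — zero-phase Butterworth filtering into the 0.01–0.1 Hz band
  in which slow CBV fluctuations track neuronal activity,
* :func:`censor_frames` — robust flagging of motion/artifact frames,
* :func:`extract_roi` — unweighted ROI averaging into 22 labelled signals,
* :func:`select_interval` — drug-anchored interval extraction (e.g. the 9-min
  baseline centred at −5 min, or the 15-min window centred at +10 min).

Invalid frames are always *masked*, never deleted: downstream correlation code
drops them pairwise, so the time axis stays anchored to the injections.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import h5py
import numpy as np
from scipy import signal

__all__ = [
    "REGIONS",
    "ROI_LABELS",
    "ImageSeries",
    "RoiTimeSeries",
    "bandpass",
    "censor_frames",
    "extract_roi",
    "select_interval",
    "save_session",
    "load_session",
]

#: The 11 bilateral regions, in canonical atlas order (coronal slice at
#: bregma +2.5 mm): infralimbic, prelimbic, cingulate area 1, secondary and
#: primary motor, primary somatosensory, granular/dysgranular insular,
#: anterior insular cortex, caudate putamen, nucleus accumbens core and shell.
REGIONS: tuple[str, ...] = (
    "IL", "PrL", "Cg1", "M2", "M1", "S1", "GIDI", "AI", "CPu", "NAcC", "NAcSh",
)

#: Canonical 22-label order: each region left then right, regions in
#: ``REGIONS`` order.  All 22×T signal arrays and 22×22 connectivity matrices
#: in this package follow this ordering.
ROI_LABELS: tuple[str, ...] = tuple(
    f"{region}-{side}" for region in REGIONS for side in ("L", "R")
)


def _check_time_axis(time_s: np.ndarray, fs: float) -> None:
    steps = np.diff(time_s)
    if len(time_s) > 1 and not np.allclose(steps, 1.0 / fs, rtol=0, atol=1e-6 / fs):
        raise ValueError("time_s must increase strictly with step 1/fs")


@dataclass
class ImageSeries:
    """A rows × cols × T CBV stack with its validity mask and time axis.

    ``time_s`` is in seconds relative to the ketamine injection (t = 0).
    ``valid`` marks frames usable for correlation; censoring only ever flips
    entries of this mask.  ``brain_mask`` (optional) marks in-brain pixels.
    """

    data: np.ndarray            # (rows, cols, T), a.u.
    time_s: np.ndarray          # (T,)
    fs: float                   # frames / s
    pixel_mm: float = 0.1
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]
    brain_mask: np.ndarray | None = None
    injections_s: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.time_s = np.asarray(self.time_s, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (rows, cols, T)")
        if self.data.shape[2] != len(self.time_s):
            raise ValueError("len(time_s) must equal the number of frames")
        _check_time_axis(self.time_s, self.fs)
        if self.valid is None:
            self.valid = np.ones(len(self.time_s), dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.valid.shape != self.time_s.shape:
            raise ValueError("valid mask must be per-frame")

    @property
    def n_frames(self) -> int:
        return self.data.shape[2]

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[:2]


@dataclass
class RoiTimeSeries:
    """22 labelled ROI-mean signals sharing one time axis and validity mask."""

    signals: np.ndarray         # (n_roi, T)
    time_s: np.ndarray
    fs: float
    labels: Sequence[str] = ROI_LABELS
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        self.time_s = np.asarray(self.time_s, dtype=float)
        if self.signals.ndim != 2:
            raise ValueError("signals must be (n_roi, T)")
        if self.signals.shape[1] != len(self.time_s):
            raise ValueError("signals and time_s disagree on T")
        if self.signals.shape[0] != len(self.labels):
            raise ValueError("one label per signal row required")
        _check_time_axis(self.time_s, self.fs)
        if self.valid is None:
            self.valid = np.ones(len(self.time_s), dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)
        if not np.all(np.isfinite(self.signals[:, self.valid])):
            raise ValueError("signals must be finite on valid frames")

    @property
    def n_frames(self) -> int:
        return self.signals.shape[1]


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def _butter_sos(low_hz: float, high_hz: float, order: int, fs: float):
    if not (0.0 < low_hz < high_hz < fs / 2.0):
        raise ValueError(
            f"band ({low_hz}, {high_hz}) Hz must satisfy 0 < low < high < fs/2 = {fs / 2}"
        )
    return signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos")


def bandpass(
    x: np.ndarray,
    low_hz: float = 0.01,
    high_hz: float = 0.1,
    order: int = 4,
    fs: float = 1.0,
    axis: int = -1,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass along ``axis``.

    The filter is applied forward and backward (``sosfiltfilt``), so no
    temporal shift is introduced relative to the injection anchor; the
    effective attenuation order is doubled.  Edges are handled by reflect
    padding of 3 × ``order`` samples.
    """
    x = np.asarray(x, dtype=float)
    sos = _butter_sos(low_hz, high_hz, order, fs)
    min_len = 6 * order + 1
    if x.shape[axis] < min_len:
        raise ValueError(
            f"series of length {x.shape[axis]} too short to filter; "
            f"need at least {min_len} samples for order {order}"
        )
    return signal.sosfiltfilt(sos, x, axis=axis, padtype="even", padlen=3 * order)


# ---------------------------------------------------------------------------
# Frame censoring
# ---------------------------------------------------------------------------

def censor_frames(series: ImageSeries, zmax: float = 4.0, window_s: float = 31.0) -> ImageSeries:
    """Flag frames whose global-mean intensity is a robust outlier.

    The per-frame global mean is compared to a centred rolling median
    (``window_s`` wide); deviations beyond ``zmax`` robust standard deviations
    (1.4826 × MAD of the deviations) mark the frame invalid.  Data values are
    untouched — censoring is masking, not deletion.
    """
    if zmax <= 0:
        raise ValueError("zmax must be positive")
    g = series.data.mean(axis=(0, 1))
    win = int(round(window_s * series.fs))
    win = max(3, win | 1)  # odd window
    med = signal.medfilt(g, kernel_size=min(win, len(g) - (1 - len(g) % 2)))
    dev = g - med
    mad = np.median(np.abs(dev - np.median(dev)))
    robust_sd = 1.4826 * mad
    if robust_sd == 0:
        robust_sd = dev.std() or 1.0
    new_valid = series.valid & (np.abs(dev) <= zmax * robust_sd)
    return replace(series, valid=new_valid)


# ---------------------------------------------------------------------------
# ROI extraction
# ---------------------------------------------------------------------------

def extract_roi(
    series: ImageSeries,
    roi_map: Mapping[str, np.ndarray],
    labels: Sequence[str] = ROI_LABELS,
) -> RoiTimeSeries:
    """Average the pixel stack over each ROI into a labelled signal set.

    ``roi_map`` maps label → (m, 2) array of (row, col) pixel indices.  The
    mean is unweighted; the validity mask propagates unchanged.
    """
    n_roi = len(labels)
    out = np.empty((n_roi, series.n_frames))
    for i, lab in enumerate(labels):
        if lab not in roi_map:
            raise ValueError(f"ROI map is missing label {lab!r}")
        px = np.asarray(roi_map[lab])
        if px.size == 0:
            raise ValueError(f"ROI {lab!r} contains no pixels")
        out[i] = series.data[px[:, 0], px[:, 1], :].mean(axis=0)
    return RoiTimeSeries(
        signals=out, time_s=series.time_s, fs=series.fs,
        labels=tuple(labels), valid=series.valid.copy(),
    )


# ---------------------------------------------------------------------------
# Interval selection
# ---------------------------------------------------------------------------

def interval_mask(time_s: np.ndarray, center_min: float, width_min: float) -> np.ndarray:
    """Boolean mask of frames in the closed interval center ± width/2 (minutes)."""
    lo = (center_min - width_min / 2.0) * 60.0
    hi = (center_min + width_min / 2.0) * 60.0
    eps = 1e-9
    return (time_s >= lo - eps) & (time_s <= hi + eps)


def select_interval(series, center_min: float, width_min: float):
    """Extract the contiguous sub-series in the closed interval (minutes).

    Works on :class:`ImageSeries` and :class:`RoiTimeSeries`.  Invalid frames
    stay in the output with their mask; correlations downstream drop them
    pairwise.  An interval extending beyond the recording raises, stating the
    available span.
    """
    t = series.time_s
    lo = (center_min - width_min / 2.0) * 60.0
    hi = (center_min + width_min / 2.0) * 60.0
    if lo < t[0] - 1e-9 or hi > t[-1] + 1e-9:
        raise ValueError(
            f"interval [{lo / 60:g}, {hi / 60:g}] min outside recording span "
            f"[{t[0] / 60:g}, {t[-1] / 60:g}] min"
        )
    sel = interval_mask(t, center_min, width_min)
    if isinstance(series, ImageSeries):
        return replace(
            series, data=series.data[:, :, sel], time_s=t[sel], valid=series.valid[sel]
        )
    if isinstance(series, RoiTimeSeries):
        return replace(
            series, signals=series.signals[:, sel], time_s=t[sel], valid=series.valid[sel]
        )
    raise TypeError(f"unsupported series type {type(series).__name__}")


# ---------------------------------------------------------------------------
# HDF5 session I/O
# ---------------------------------------------------------------------------

def save_session(path, series: ImageSeries, roi_map: Mapping[str, np.ndarray] | None = None,
                 meta: Mapping[str, str] | None = None) -> None:
    """Write a session as HDF5: /cbv [rows×cols×T], /valid, /time_s (+ ROI layout)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("cbv", data=series.data)
        f.create_dataset("valid", data=series.valid)
        f.create_dataset("time_s", data=series.time_s)
        if series.brain_mask is not None:
            f.create_dataset("brain_mask", data=series.brain_mask)
        f.attrs["fs"] = series.fs
        f.attrs["pixel_mm"] = series.pixel_mm
        for k, v in (series.injections_s or {}).items():
            f.attrs[f"injection_{k}_s"] = v
        if roi_map is not None:
            grp = f.create_group("roi_labels")
            for lab, px in roi_map.items():
                grp.create_dataset(lab, data=np.asarray(px))
        for k, v in (meta or {}).items():
            f.attrs[f"meta_{k}"] = v


def load_session(path) -> tuple[ImageSeries, dict[str, np.ndarray]]:
    """Read a session written by :func:`save_session`."""
    with h5py.File(path, "r") as f:
        injections = {
            k[len("injection_"):-2]: float(f.attrs[k])
            for k in f.attrs if k.startswith("injection_") and k.endswith("_s")
        }
        series = ImageSeries(
            data=f["cbv"][()],
            time_s=f["time_s"][()],
            fs=float(f.attrs["fs"]),
            pixel_mm=float(f.attrs["pixel_mm"]),
            valid=f["valid"][()],
            brain_mask=f["brain_mask"][()] if "brain_mask" in f else None,
            injections_s=injections,
        )
        roi_map = {}
        if "roi_labels" in f:
            roi_map = {lab: f["roi_labels"][lab][()] for lab in f["roi_labels"]}
    return series, roi_map
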