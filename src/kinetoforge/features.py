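"""Foci detection and the 13 kinetochore/SPB image features.

Operates on processed 50x50x3 16-bit RGB images in which the green slot
carries the kinetochore marker (Cse4 or Nuf2) and the red slot the SPB
marker (Spc29). Two foci are expected in each channel; images in which
either pair cannot be found are flagged and excluded rather than raising,
mirroring how incomplete experimental crops are discarded.

Distances are expressed as fractions of the spindle length (the SPB-SPB
distance), heights as FWHM in pixels, and intensity statistics in counts.
"""

from __future__ import annotations

from dataclasses import dataclass, fields as dc_fields

import numpy as np
import pandas as pd
from scipy import ndimage, optimize

__all__ = ["Focus", "FeatureRecord", "FEATURE_NAMES", "detect_foci",
           "spindle_axis", "spot_height", "linescan_std", "region_stats",
           "distances", "extract_features", "features_to_frame"]

GREEN, RED = 1, 0     # RGB slots of kinetochore and SPB markers


@dataclass
class Focus:
    """One detected spot: brightest pixel plus a subpixel-refined center."""

    row: int
    col: int
    sub_row: float
    sub_col: float
    peak: float
    channel: str = ""

    @property
    def pixel(self) -> np.ndarray:
        return np.array([self.row, self.col], dtype=float)

    @property
    def center(self) -> np.ndarray:
        return np.array([self.sub_row, self.sub_col], dtype=float)


@dataclass
class FeatureRecord:
    """The 13 per-image features, in canonical (importance-table) order."""

    kinetochore_distance_to_spb: float
    kinetochore_x_distance: float
    spb_mean_intensity: float
    spb_height: float
    spb_std_y: float
    spb_std_x: float
    spb_std: float
    kinetochore_height: float
    kinetochore_std: float
    kinetochore_std_y: float
    kk_distance: float
    kinetochore_mean_intensity: float
    kinetochore_std_x: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f.name) for f in dc_fields(self)],
                        dtype=float)


FEATURE_NAMES = [f.name for f in dc_fields(FeatureRecord)]


def _gaussian2d(params, rr, cc):
    amp, r0, c0, sigma, off = params
    return off + amp * np.exp(-((rr - r0)**2 + (cc - c0)**2) / (2.0 * sigma**2))


def _refine_subpixel(ch: np.ndarray, row: int, col: int, half: int = 3
                     ) -> tuple[float, float]:
    """Refine a peak position by a local 2D Gaussian fit.

    Falls back to the intensity centroid of the window (and ultimately the
    pixel itself) if the fit fails or wanders out of the window.
    """
    r0, r1 = max(row - half, 0), min(row + half + 1, ch.shape[0])
    c0, c1 = max(col - half, 0), min(col + half + 1, ch.shape[1])
    win = ch[r0:r1, c0:c1].astype(float)
    rr, cc = np.mgrid[r0:r1, c0:c1]
    off0 = win.min()
    amp0 = max(win.max() - off0, 1.0)
    x0 = [amp0, float(row), float(col), 1.5, off0]
    try:
        res = optimize.least_squares(
            lambda p: (_gaussian2d(p, rr, cc) - win).ravel(), x0,
            bounds=([0, r0, c0, 0.3, -np.inf], [np.inf, r1, c1, 10.0, np.inf]),
            max_nfev=200)
        if res.success and abs(res.x[1] - row) <= half and abs(res.x[2] - col) <= half:
            return float(res.x[1]), float(res.x[2])
    except Exception:
        pass
    w = np.clip(win - off0, 0.0, None)
    if w.sum() > 0:
        return float((rr * w).sum() / w.sum()), float((cc * w).sum() / w.sum())
    return float(row), float(col)


def detect_foci(image: np.ndarray, channel: int, n_expected: int,
                mad_k: float = 5.0, min_separation: float = 3.0,
                relative_floor: float = 0.3) -> list[Focus]:
    """Detect up to ``n_expected`` foci in one channel of an RGB image.

    Candidate local maxima above a robust threshold (median + k*MAD) are
    pruned to a minimum mutual separation (brightest first), required to
    reach ``relative_floor`` of the brightest candidate's
    background-subtracted amplitude (so residual noise bumps never pass as
    a second focus), and refined to subpixel centers by a local Gaussian
    fit. Returned foci are sorted left to right (by column). Fewer than
    ``n_expected`` results means the image should be flagged by the caller.
    """
    if n_expected not in (1, 2):
        raise ValueError("n_expected must be 1 or 2")
    ch = np.asarray(image, dtype=float)
    if ch.ndim == 3:
        ch = ch[..., channel]
    med = np.median(ch)
    mad = np.median(np.abs(ch - med))
    scale = mad if mad > 0 else (ch.std() / 5.0)
    thresh = med + mad_k * scale
    local_max = ndimage.maximum_filter(ch, size=3, mode="nearest")
    cand = np.argwhere((ch >= local_max) & (ch > thresh))
    if len(cand) == 0:
        return []
    order = np.argsort(ch[cand[:, 0], cand[:, 1]])[::-1]
    cand = cand[order]
    amp_floor = med + relative_floor * (ch[tuple(cand[0])] - med)
    kept: list[np.ndarray] = []
    for rc in cand:
        if ch[tuple(rc)] < amp_floor:
            break
        if all(np.hypot(*(rc - k)) >= min_separation for k in kept):
            kept.append(rc)
        if len(kept) == n_expected:
            break
    foci = []
    label = {GREEN: "green", RED: "red"}.get(channel, str(channel))
    for r, c in kept:
        sr, sc = _refine_subpixel(ch, int(r), int(c))
        foci.append(Focus(int(r), int(c), sr, sc, float(ch[r, c]), label))
    foci.sort(key=lambda f: f.col)
    return foci


def spindle_axis(spb_foci: list[Focus]) -> tuple[np.ndarray, float]:
    """Unit vector (row, col) between the SPB brightest pixels, and length."""
    if len(spb_foci) != 2:
        raise ValueError("spindle_axis requires exactly 2 SPB foci")
    vec = spb_foci[1].pixel - spb_foci[0].pixel
    length = float(np.hypot(*vec))
    if length == 0:
        raise ValueError("degenerate spindle axis: coincident SPB foci")
    return vec / length, length


def _perp(axis: np.ndarray) -> np.ndarray:
    return np.array([-axis[1], axis[0]])


def _sample_line(ch: np.ndarray, points: np.ndarray) -> np.ndarray | None:
    """Bilinear samples at (row, col) points; None if any point off-image."""
    if points[:, 0].min() < 0 or points[:, 0].max() > ch.shape[0] - 1 \
            or points[:, 1].min() < 0 or points[:, 1].max() > ch.shape[1] - 1:
        return None
    return ndimage.map_coordinates(ch.astype(float), points.T, order=1)


def _fwhm(profile: np.ndarray, spacing: float = 1.0) -> float | None:
    """FWHM of a sampled profile by linear interpolation around its peak."""
    p = profile - profile.min()
    m = p.max()
    if m <= 0:
        return None
    half = m / 2.0
    i = int(np.argmax(p))

    def _cross(idx_range):
        prev = i
        for j in idx_range:
            if p[j] < half:
                frac = (p[prev] - half) / (p[prev] - p[j])
                return abs(prev - i) + frac
            prev = j
        return None

    left = _cross(range(i - 1, -1, -1))
    right = _cross(range(i + 1, len(p)))
    if left is None or right is None:
        return None
    return float((left + right) * spacing)


def spot_height(image: np.ndarray, focus: Focus, axis: np.ndarray,
                channel: int | None = None) -> float | None:
    """FWHM perpendicular to the spindle of the focus' 7x15 neighborhood.

    A 7 (along-axis) x 15 (perpendicular) region about the brightest pixel
    is sampled on rotated axes by bilinear interpolation, max-projected
    along the axis direction to a 15-sample perpendicular profile, and the
    FWHM of that profile (minimum-subtracted) is measured in pixels.
    """
    ch = _as_channel(image, channel, focus)
    perp = _perp(axis)
    along = np.arange(-3, 4)
    across = np.arange(-7, 8)
    grid = (focus.pixel[None, None, :]
            + along[:, None, None] * axis[None, None, :]
            + across[None, :, None] * perp[None, None, :])
    samples = _sample_line(ch, grid.reshape(-1, 2))
    if samples is None:
        return None
    profile = samples.reshape(7, 15).max(axis=0)
    return _fwhm(profile)


def linescan_std(image: np.ndarray, focus: Focus, direction: str,
                 axis: np.ndarray, length: int = 15,
                 channel: int | None = None) -> float | None:
    """Sample std of a 15-px line scan through the brightest pixel.

    ``direction`` is ``"parallel"`` (along the spindle axis) or
    ``"perpendicular"``.
    """
    if direction not in ("parallel", "perpendicular"):
        raise ValueError("direction must be 'parallel' or 'perpendicular'")
    ch = _as_channel(image, channel, focus)
    vec = axis if direction == "parallel" else _perp(axis)
    half = length // 2
    offs = np.arange(-half, length - half)
    pts = focus.pixel[None, :] + offs[:, None] * vec[None, :]
    samples = _sample_line(ch, pts)
    if samples is None:
        return None
    return float(np.std(samples, ddof=1))


def region_stats(image: np.ndarray, focus: Focus, size: int = 5,
                 channel: int | None = None) -> tuple[float, float] | None:
    """Mean and sample std of the size x size block around the brightest pixel."""
    ch = _as_channel(image, channel, focus)
    half = size // 2
    r, c = focus.row, focus.col
    if r - half < 0 or c - half < 0 or r + half >= ch.shape[0] or c + half >= ch.shape[1]:
        return None
    block = ch[r - half:r + half + 1, c - half:c + half + 1].astype(float)
    return float(block.mean()), float(block.std(ddof=1))


def _as_channel(image: np.ndarray, channel: int | None, focus: Focus) -> np.ndarray:
    img = np.asarray(image)
    if img.ndim == 2:
        return img
    if channel is None:
        channel = {"green": GREEN, "red": RED}.get(focus.channel, GREEN)
    return img[..., channel]


def distances(k_foci: list[Focus], spb_foci: list[Focus], axis: np.ndarray,
              spindle_length: float) -> tuple[float, float, float]:
    """Normalized distances: (kk_distance, mean K-to-SPB, mean K x-distance).

    Each kinetochore focus is paired to its nearest SPB; Euclidean and
    along-axis distances are averaged over the two kinetochores. All values
    are divided by the spindle length. Subpixel centers are used.
    """
    if len(k_foci) != 2 or len(spb_foci) != 2:
        raise ValueError("need 2 kinetochore and 2 SPB foci")
    kk = float(np.hypot(*(k_foci[0].center - k_foci[1].center))) / spindle_length
    d_list, x_list = [], []
    for k in k_foci:
        deltas = [k.center - s.center for s in spb_foci]
        dists = [np.hypot(*d) for d in deltas]
        j = int(np.argmin(dists))
        d_list.append(dists[j] / spindle_length)
        x_list.append(abs(float(deltas[j] @ axis)) / spindle_length)
    return kk, float(np.mean(d_list)), float(np.mean(x_list))


def extract_features(image: np.ndarray) -> tuple[FeatureRecord | None, str | None]:
    """Compute all 13 features of a processed image, or flag it.

    Returns ``(record, None)`` on success or ``(None, reason)`` when foci
    are missing or a measurement window falls off the image. Per-focus
    quantities are averaged over the two foci of each channel.
    """
    img = np.asarray(image)
    k_foci = detect_foci(img, GREEN, 2)
    if len(k_foci) < 2:
        return None, "insufficient kinetochore foci"
    spb_foci = detect_foci(img, RED, 2)
    if len(spb_foci) < 2:
        return None, "insufficient SPB foci"
    try:
        axis, length = spindle_axis(spb_foci)
    except ValueError as exc:
        return None, str(exc)

    def _mean(vals):
        if any(v is None for v in vals):
            return None
        return float(np.mean(vals))

    spb_stats = [region_stats(img, f, channel=RED) for f in spb_foci]
    k_stats = [region_stats(img, f, channel=GREEN) for f in k_foci]
    if any(s is None for s in spb_stats + k_stats):
        return None, "5x5 region off image"
    values = dict(
        spb_mean_intensity=_mean([s[0] for s in spb_stats]),
        spb_std=_mean([s[1] for s in spb_stats]),
        kinetochore_mean_intensity=_mean([s[0] for s in k_stats]),
        kinetochore_std=_mean([s[1] for s in k_stats]),
        spb_height=_mean([spot_height(img, f, axis, RED) for f in spb_foci]),
        kinetochore_height=_mean([spot_height(img, f, axis, GREEN) for f in k_foci]),
        spb_std_y=_mean([linescan_std(img, f, "perpendicular", axis, channel=RED)
                         for f in spb_foci]),
        spb_std_x=_mean([linescan_std(img, f, "parallel", axis, channel=RED)
                         for f in spb_foci]),
        kinetochore_std_y=_mean([linescan_std(img, f, "perpendicular", axis,
                                              channel=GREEN) for f in k_foci]),
        kinetochore_std_x=_mean([linescan_std(img, f, "parallel", axis,
                                              channel=GREEN) for f in k_foci]),
    )
    if any(v is None for v in values.values()):
        return None, "measurement window off image or flat profile"
    kk, d_spb, d_x = distances(k_foci, spb_foci, axis, length)
    values.update(kk_distance=kk, kinetochore_distance_to_spb=d_spb,
                  kinetochore_x_distance=d_x)
    return FeatureRecord(**values), None


def features_to_frame(records: list[FeatureRecord],
                      labels: list | None = None,
                      image_ids: list | None = None) -> pd.DataFrame:
    """Stack feature records into a DataFrame (one row per retained image)."""
    data = np.array([r.as_array() for r in records]).reshape(-1, len(FEATURE_NAMES))
    df = pd.DataFrame(data, columns=FEATURE_NAMES)
    if image_ids is not None:
        df.insert(0, "image_id", image_ids)
    if labels is not None:
        df["class_label"] = labels
    return df
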