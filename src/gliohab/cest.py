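"""pH-weighted CEST mapping: z-spectra to MTRasym(3.0 ppm) maps.

Amine CEST MRI saturates exchangeable amine protons at +3.0 ppm from water
and reads out the transferred saturation as a loss in the bulk-water signal.
Because amine–water proton exchange is base-catalyzed, the asymmetry of the
magnetization-transfer ratio at 3.0 ppm,

    MTRasym(3.0 ppm) = S(-3.0 ppm)/S0 - S(+3.0 ppm)/S0,

is sensitive to tissue pH.  This module turns a sampled z-spectrum volume
(water signal S as a function of saturation offset omega, in ppm relative to
water) into a voxel-wise MTRasym map.  The band value at +/-3.0 ppm is taken
as an integral of width 0.4 ppm, realized as the mean of S/S0 over offsets in
[2.8, 3.2] ppm (and the mirrored band); on a regular 0.1-ppm offset grid this
equals a normalized rectangle-rule integral.

Static-field (B0) inhomogeneity shifts every voxel's z-spectrum center and
must be removed before asymmetry analysis.  A simplified two-stage correction
is provided: k-means clustering of the normalized z-spectra followed by an
inverted-Lorentzian fit to each cluster-mean spectrum near the water
resonance, whose fitted center is the per-voxel shift estimate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit
from sklearn.cluster import KMeans

logger = logging.getLogger(__name__)

#: Saturation-offset scheme used throughout: three bands at 0.1-ppm spacing,
#: -3.5..-2.5, -0.3..+0.3 and +2.5..+3.5 ppm (29 points).
AMINE_OFFSET_PPM = 3.0
DEFAULT_BAND_HALFWIDTH_PPM = 0.2
DEFAULT_MAX_SHIFT_PPM = 1.0
WATER_BAND_PPM = 0.3


def default_offsets() -> np.ndarray:
    """Return the 29-point three-band saturation-offset grid (ppm)."""
    return np.round(
        np.concatenate(
            [
                np.arange(-3.5, -2.5 + 1e-9, 0.1),
                np.arange(-0.3, 0.3 + 1e-9, 0.1),
                np.arange(2.5, 3.5 + 1e-9, 0.1),
            ]
        ),
        6,
    )


@dataclass
class ZSpectrumVolume:
    """A sampled CEST z-spectrum volume with its unsaturated reference.

    Parameters
    ----------
    signal
        Saturated water signal.  Shape ``(x, y, z, n_offsets)`` for
        single-echo data, or ``(n_echoes, x, y, z, n_offsets)`` when a
        leading echo dimension is present (SAGE readouts).
    offsets_ppm
        Strictly increasing saturation offsets, ppm relative to water.
    s0
        Unsaturated reference signal, shape ``(x, y, z)`` (or with a leading
        echo dimension matching ``signal``).
    mask
        Boolean volume of valid voxels, shape ``(x, y, z)``.
    """

    signal: np.ndarray
    offsets_ppm: np.ndarray
    s0: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        self.offsets_ppm = np.asarray(self.offsets_ppm, dtype=float)
        self.s0 = np.asarray(self.s0, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.offsets_ppm.ndim != 1 or len(self.offsets_ppm) < 2:
            raise ValueError("offsets_ppm must be a 1-D array of >= 2 offsets")
        if np.any(np.diff(self.offsets_ppm) <= 0):
            raise ValueError("offsets_ppm must be strictly increasing")
        if self.signal.shape[-1] != len(self.offsets_ppm):
            raise ValueError(
                f"signal last axis ({self.signal.shape[-1]}) must match "
                f"number of offsets ({len(self.offsets_ppm)})"
            )
        if self.signal.ndim not in (4, 5):
            raise ValueError("signal must be 4-D or (with echoes) 5-D")
        if self.signal.shape[:-1] != self.s0.shape:
            raise ValueError(
                f"s0 shape {self.s0.shape} does not match signal "
                f"{self.signal.shape[:-1]}"
            )
        if self.mask.shape != self.spatial_shape:
            raise ValueError(
                f"mask shape {self.mask.shape} != spatial shape {self.spatial_shape}"
            )
        s0_in_mask = self.s0[..., self.mask] if self.has_echoes else self.s0[self.mask]
        if s0_in_mask.size and not np.all(s0_in_mask > 0):
            raise ValueError("s0 must be positive wherever mask is true")

    @property
    def has_echoes(self) -> bool:
        return self.signal.ndim == 5

    @property
    def n_echoes(self) -> int:
        return self.signal.shape[0] if self.has_echoes else 1

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.signal.shape[-4:-1]

    def normalized(self) -> np.ndarray:
        """S/S0, shape ``spatial_shape + (n_offsets,)`` (single echo only)."""
        if self.has_echoes:
            raise ValueError("average echoes before normalizing")
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.signal / self.s0[..., None]


@dataclass
class B0ShiftMap:
    """Per-voxel water-center offset delta (ppm) and a fit-quality volume."""

    delta_ppm: np.ndarray
    fit_quality: np.ndarray
    max_shift_ppm: float = DEFAULT_MAX_SHIFT_PPM


@dataclass
class MTRAsymMap:
    """Voxel-wise MTRasym(3.0 ppm), dimensionless ratio; NaN outside mask."""

    values: np.ndarray
    mask: np.ndarray
    band_halfwidth_ppm: float = DEFAULT_BAND_HALFWIDTH_PPM

    def as_percent(self) -> np.ndarray:
        """Values scaled by 100 (percent formatting; storage stays a ratio)."""
        return self.values * 100.0


def average_sage_echoes(zspec: ZSpectrumVolume) -> ZSpectrumVolume:
    """Average the first and second gradient echoes of a SAGE acquisition.

    Echoes beyond the second are ignored.  S0 is averaged identically so the
    normalized spectrum is consistent.
    """
    if not zspec.has_echoes or zspec.n_echoes < 2:
        raise ValueError(
            "echo averaging requires a leading echo dimension with >= 2 echoes"
        )
    return ZSpectrumVolume(
        signal=zspec.signal[:2].mean(axis=0),
        offsets_ppm=zspec.offsets_ppm,
        s0=zspec.s0[:2].mean(axis=0),
        mask=zspec.mask,
    )


def inverted_lorentzian(omega: np.ndarray, a: float, gamma: float, delta: float) -> np.ndarray:
    """Normalized z-spectrum model 1 - A*Gamma^2 / (Gamma^2 + (omega-delta)^2)."""
    return 1.0 - a * gamma**2 / (gamma**2 + (omega - delta) ** 2)


def _fit_water_center(offsets: np.ndarray, spectrum: np.ndarray,
                      max_shift: float) -> tuple[float, float]:
    """Fit the inverted Lorentzian to near-water points; return (delta, resid norm)."""
    i_min = int(np.argmin(spectrum))
    p0 = (
        float(np.clip(1.0 - spectrum[i_min], 1e-3, 1.0)),
        0.5,
        float(np.clip(offsets[i_min], -max_shift, max_shift)),
    )
    try:
        popt, _ = curve_fit(
            inverted_lorentzian,
            offsets,
            spectrum,
            p0=p0,
            bounds=([1e-6, 0.02, -max_shift], [1.5, 10.0, max_shift]),
            maxfev=2000,
        )
        delta = float(popt[2])
        resid = float(np.linalg.norm(inverted_lorentzian(offsets, *popt) - spectrum))
    except RuntimeError:  # no convergence: fall back to the sampled minimum
        delta = p0[2]
        resid = float("inf")
    return delta, resid


def estimate_b0_shift(
    zspec: ZSpectrumVolume,
    n_clusters: int = 32,
    seed: int = 0,
    max_shift_ppm: float = DEFAULT_MAX_SHIFT_PPM,
    water_band_ppm: float = WATER_BAND_PPM,
) -> B0ShiftMap:
    """Estimate the per-voxel B0 shift by cluster-then-Lorentzian-fit.

    Normalized z-spectra of masked voxels are grouped by k-means
    (``n_clusters`` groups, deterministic for a given ``seed``); an inverted
    Lorentzian is fit to each cluster-mean spectrum restricted to the
    near-water offsets (|omega| <= ``water_band_ppm``), and every voxel
    inherits its cluster's fitted center.  This is a simplified
    re-implementation of the two-stage clustering/fitting style of
    correction; it assumes the shift field is piecewise-smooth enough to be
    captured by the cluster structure.
    """
    near = np.abs(zspec.offsets_ppm) <= water_band_ppm + 1e-9
    if near.sum() < 4:
        raise ValueError(
            f"need >= 4 near-water offsets (|omega| <= {water_band_ppm} ppm), "
            f"found {int(near.sum())}"
        )
    if not zspec.mask.any():
        raise ValueError("mask is empty")

    z = zspec.normalized()[zspec.mask]  # (n_vox, n_offsets)
    uniq = np.unique(z, axis=0)
    k = int(min(n_clusters, len(uniq)))
    if k == 1:
        labels = np.zeros(len(z), dtype=int)
        centers = uniq
    else:
        km = KMeans(n_clusters=k, random_state=seed, n_init=4)
        labels = km.fit_predict(z)
        centers = km.cluster_centers_

    w_off = zspec.offsets_ppm[near]
    deltas = np.empty(k)
    resids = np.empty(k)
    for j in range(k):
        deltas[j], resids[j] = _fit_water_center(w_off, centers[j][near], max_shift_ppm)

    delta_vol = np.full(zspec.spatial_shape, np.nan)
    qual_vol = np.full(zspec.spatial_shape, np.nan)
    delta_vol[zspec.mask] = deltas[labels]
    qual_vol[zspec.mask] = resids[labels]
    return B0ShiftMap(delta_vol, qual_vol, max_shift_ppm=max_shift_ppm)


def b0_correct_zspectrum(zspec: ZSpectrumVolume, b0: B0ShiftMap) -> ZSpectrumVolume:
    """Re-sample each voxel's z-spectrum at omega + delta (shift removal).

    Monotone piecewise-linear interpolation over the offset grid; target
    positions outside the sampled range become NaN (missing) for that voxel
    rather than being extrapolated.  Voxels whose |delta| exceeds the
    configured bound are removed from the mask.
    """
    if b0.delta_ppm.shape != zspec.spatial_shape:
        raise ValueError("B0 map shape does not match z-spectrum volume")
    if zspec.has_echoes:
        raise ValueError("average echoes before B0 correction")

    mask = zspec.mask.copy()
    over = mask & (np.abs(np.nan_to_num(b0.delta_ppm, nan=np.inf)) > b0.max_shift_ppm)
    if over.any():
        logger.warning("B0 correction: %d voxels exceed |delta| bound, masked out",
                       int(over.sum()))
        mask &= ~over

    offsets = zspec.offsets_ppm
    delta = np.where(mask, np.nan_to_num(b0.delta_ppm, nan=0.0), 0.0)
    pos = offsets[None, None, None, :] + delta[..., None]

    idx = np.clip(np.searchsorted(offsets, pos), 1, len(offsets) - 1)
    x0 = offsets[idx - 1]
    x1 = offsets[idx]
    frac = (pos - x0) / (x1 - x0)
    s_lo = np.take_along_axis(zspec.signal, idx - 1, axis=-1)
    s_hi = np.take_along_axis(zspec.signal, idx, axis=-1)
    out = (1.0 - frac) * s_lo + frac * s_hi
    eps = 1e-9 * (offsets[-1] - offsets[0])  # tolerate float fuzz at the ends
    out[(pos < offsets[0] - eps) | (pos > offsets[-1] + eps)] = np.nan
    out[~mask] = zspec.signal[~mask]
    return ZSpectrumVolume(out, offsets, zspec.s0, mask)


def mtr_asym_at_3ppm(
    offsets_ppm: Sequence[float],
    signal: Sequence[float],
    s0: float,
    band_halfwidth_ppm: float = DEFAULT_BAND_HALFWIDTH_PPM,
) -> float:
    """MTRasym(3.0 ppm) for a single voxel's (omega, S) spectrum.

    Returns mean(S/S0 over [-3-h, -3+h]) - mean(S/S0 over [+3-h, +3+h]),
    the band-average realization of the width-2h integral around the amine
    resonance.  NaN samples inside a band are ignored; a band with no finite
    sample raises.
    """
    offsets = np.asarray(offsets_ppm, dtype=float)
    sig = np.asarray(signal, dtype=float)
    if s0 <= 0:
        raise ValueError("s0 must be positive")
    h = band_halfwidth_ppm
    vals = []
    for name, center in (("negative", -AMINE_OFFSET_PPM), ("positive", AMINE_OFFSET_PPM)):
        sel = np.abs(offsets - center) <= h + 1e-9
        band = sig[sel] / s0
        band = band[np.isfinite(band)]
        if band.size == 0:
            raise ValueError(f"no finite samples in the {name} band around {center} ppm")
        vals.append(band.mean())
    return float(vals[0] - vals[1])


def compute_mtr_asym_map(
    zspec: ZSpectrumVolume,
    band_halfwidth_ppm: float = DEFAULT_BAND_HALFWIDTH_PPM,
) -> MTRAsymMap:
    """Voxel-wise MTRasym(3.0 ppm) within the mask; NaN outside.

    Voxels whose corrected spectrum has no finite sample in either band are
    dropped from the output mask (their count is logged).
    """
    if zspec.has_echoes:
        raise ValueError("average echoes before computing the MTRasym map")
    if not zspec.mask.any():
        logger.warning("compute_mtr_asym_map: empty mask, returning empty map")
        return MTRAsymMap(np.full(zspec.spatial_shape, np.nan), zspec.mask.copy(),
                          band_halfwidth_ppm)

    h = band_halfwidth_ppm
    neg = np.abs(zspec.offsets_ppm + AMINE_OFFSET_PPM) <= h + 1e-9
    pos = np.abs(zspec.offsets_ppm - AMINE_OFFSET_PPM) <= h + 1e-9
    for name, sel in (("negative", neg), ("positive", pos)):
        if not sel.any():
            raise ValueError(f"offset grid has no samples in the {name} band")

    ratio = zspec.normalized()
    import warnings
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.filterwarnings("ignore", "Mean of empty slice", RuntimeWarning)
        values = np.nanmean(ratio[..., neg], axis=-1) - np.nanmean(ratio[..., pos], axis=-1)

    mask = zspec.mask & np.isfinite(values)
    dropped = int(zspec.mask.sum() - mask.sum())
    if dropped:
        logger.warning("compute_mtr_asym_map: %d voxels had an empty band and "
                       "were masked out", dropped)
    values = np.where(mask, values, np.nan)
    return MTRAsymMap(values, mask, band_halfwidth_ppm)
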