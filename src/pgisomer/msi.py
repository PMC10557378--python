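"""Line-scan MSI assembly, one-point quantitation, filtering and imaging.

Pixels are defined by the MS³ duty cycle within each scanned line: pixel
width (μm) = stage speed (mm/s) × 1000 × cycle period (s); pixel height is
the cross-scan line step.  Interlaced SIM (precursor) scans are aligned to
pixels by nearest scan time.  Invalid pixels are carried as NaN plus an
explicit mask and never enter statistics silently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .calibration import RAW_RANGE, IsomerComposition, IsomerModel, predict
from .spectra import MassSpectrum, ProductIonChannel, TripletAbundance, extract_channel

__all__ = [
    "GridGeometry",
    "IonImage",
    "ROIResult",
    "assemble_grid",
    "quantify_channel",
    "tissue_mask",
    "robust_noise",
    "snr_filter",
    "predict_image",
    "render_fraction",
    "roi_stats",
    "MASK_THRESHOLD",
    "MIN_SNR",
]

#: Tissue-mask intensity threshold on the shared MS³ product-ion channel
#: (m/z 333.2); pixels at or above the threshold are retained.
MASK_THRESHOLD = 30.0

#: S/N cutoff: a pixel's channel is included iff S/N is strictly above 5.
MIN_SNR = 5.0


@dataclass(frozen=True)
class GridGeometry:
    """Line-scan acquisition geometry."""

    stage_speed: float  # mm/s along the scan (x) axis
    cycle_period: float  # s per full spectral duty cycle
    line_step: float  # μm between lines (y axis)
    n_lines: int = 0

    def __post_init__(self):
        if min(self.stage_speed, self.cycle_period, self.line_step) <= 0:
            raise ValueError("geometry parameters must be positive")

    @staticmethod
    def from_rate(stage_speed: float, cycle_rate_hz: float, line_step: float, n_lines: int = 0):
        """Construct from a duty-cycle *rate* in Hz (period = 1/rate)."""
        return GridGeometry(stage_speed, 1.0 / cycle_rate_hz, line_step, n_lines)

    @property
    def pixel_size(self) -> tuple[float, float]:
        """(width, height) in μm; e.g. 0.02 mm/s × 1.55 s → 31 μm wide."""
        return (self.stage_speed * 1000.0 * self.cycle_period, self.line_step)


@dataclass
class IonImage:
    """2-D pixel grid with physical pixel size, validity mask and units."""

    values: np.ndarray
    pixel_size: tuple[float, float]
    mask: np.ndarray | None = None
    units: str = "counts"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.mask is None:
            self.mask = np.isfinite(self.values)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.values.shape:
            raise ValueError("values and mask must share shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def valid_values(self) -> np.ndarray:
        return self.values[self.mask & np.isfinite(self.values)]


@dataclass(frozen=True)
class ROIResult:
    mean_pge2: float
    mean_pgd2: float
    mean_d12: float
    sd_pge2: float
    sd_pgd2: float
    sd_d12: float
    n_pixels: int

    def means(self) -> np.ndarray:
        return np.array([self.mean_pge2, self.mean_pgd2, self.mean_d12])

    def sds(self) -> np.ndarray:
        return np.array([self.sd_pge2, self.sd_pgd2, self.sd_d12])


def assemble_grid(
    line_streams: Sequence[Iterable[MassSpectrum]],
    geom: GridGeometry,
    channels: Sequence[ProductIonChannel],
) -> dict[str, IonImage]:
    """Assemble per-channel ion images from time-ordered line scans.

    Pixel columns within a line follow MS³ scan order; channels declared with
    ``ms_level == 1`` are read from the nearest-in-time SIM/MS¹ scan instead.
    Lines shorter than the longest one are padded with NaN (masked out).
    Returns a dict label → IonImage.
    """
    if not line_streams:
        raise ValueError("no line streams supplied")
    per_line: list[tuple[list[MassSpectrum], list[MassSpectrum]]] = []
    for li, stream in enumerate(line_streams):
        scans = sorted(stream, key=lambda s: s.scan_time)
        if not scans:
            raise ValueError(f"line {li} contains no scans")
        ms3 = [s for s in scans if s.ms_level >= 2]
        ms1 = [s for s in scans if s.ms_level == 1]
        if not ms3:
            raise ValueError(f"line {li} contains no pixel-defining MSⁿ scans")
        per_line.append((ms3, ms1))

    n_lines = len(per_line)
    n_cols = max(len(ms3) for ms3, _ in per_line)
    images = {
        ch.label: IonImage(
            np.full((n_lines, n_cols), np.nan), geom.pixel_size, units="counts"
        )
        for ch in channels
    }
    if len(images) != len(channels):
        raise ValueError("channel labels must be unique")

    for li, (ms3, ms1) in enumerate(per_line):
        ms1_times = np.array([s.scan_time for s in ms1]) if ms1 else None
        for px, pixel_scan in enumerate(ms3):
            for ch in channels:
                if ch.ms_level == 1:
                    if ms1_times is None:
                        continue
                    src = ms1[int(np.argmin(np.abs(ms1_times - pixel_scan.scan_time)))]
                else:
                    src = pixel_scan
                images[ch.label].values[li, px] = extract_channel(src, ch)
    for img in images.values():
        img.mask = np.isfinite(img.values)
    return images


def quantify_channel(
    analyte: IonImage, standard: IonImage, standard_conc: float
) -> IonImage:
    """One-point quantitation: (analyte / internal standard) × concentration.

    Output units are those of ``standard_conc`` (μM in the intended use).
    Pixels where the standard intensity is zero or either input is invalid
    are invalid in the output.
    """
    if analyte.shape != standard.shape:
        raise ValueError("analyte and standard images must share shape")
    if standard_conc <= 0:
        raise ValueError("standard concentration must be positive")
    ok = analyte.mask & standard.mask & (standard.values > 0)
    values = np.full(analyte.shape, np.nan)
    values[ok] = analyte.values[ok] / standard.values[ok] * standard_conc
    return IonImage(values, analyte.pixel_size, mask=ok, units="uM")


def tissue_mask(reference: IonImage, threshold: float = MASK_THRESHOLD) -> np.ndarray:
    """Boolean tissue mask: reference channel intensity ≥ threshold (inclusive)."""
    with np.errstate(invalid="ignore"):
        return np.where(np.isfinite(reference.values), reference.values >= threshold, False)


def robust_noise(values: np.ndarray) -> float:
    """Robust noise level of off-tissue intensities: median + 1.4826 × MAD."""
    v = values[np.isfinite(values)]
    if v.size == 0:
        raise ValueError("no off-tissue pixels available for noise estimation")
    med = float(np.median(v))
    mad = float(np.median(np.abs(v - med)))
    return med + 1.4826 * mad


def snr_filter(
    channel_images: Mapping[str, IonImage],
    off_tissue: np.ndarray,
    min_snr: float = MIN_SNR,
    noise_levels: Mapping[str, float] | None = None,
) -> dict[str, np.ndarray]:
    """Per-channel pixel inclusion grids based on S/N against off-tissue noise.

    The per-channel noise level is the robust scale of that channel's
    off-tissue pixel intensities (unless supplied via ``noise_levels``); a
    pixel's channel is included iff intensity / noise is strictly above
    ``min_snr``.  Requires ≥ 20 off-tissue pixels for a stable estimate.
    """
    off_tissue = np.asarray(off_tissue, dtype=bool)
    inclusion: dict[str, np.ndarray] = {}
    for label, img in channel_images.items():
        if noise_levels is not None and label in noise_levels:
            noise = float(noise_levels[label])
        else:
            off_vals = img.values[off_tissue & np.isfinite(img.values)]
            if off_vals.size < 20:
                raise ValueError(
                    f"channel {label}: only {off_vals.size} off-tissue pixels; "
                    "need >= 20 to estimate noise (or pass noise_levels)"
                )
            noise = robust_noise(off_vals)
        with np.errstate(invalid="ignore", divide="ignore"):
            if noise > 0:
                snr = img.values / noise
                grid = np.where(np.isfinite(snr), snr > min_snr, False)
            else:
                grid = np.where(np.isfinite(img.values), img.values > 0, False)
        inclusion[label] = grid & img.mask
    return inclusion


def predict_image(
    model: IsomerModel,
    channel_images: Mapping[str, IonImage],
    mask: np.ndarray,
    inclusion: Mapping[str, np.ndarray] | None = None,
) -> tuple[dict[str, IonImage], np.ndarray]:
    """Pixel-wise isomer composition prediction over a masked, filtered grid.

    ``channel_images`` must carry labels '331', '333', '341'.  A pixel is
    predicted only when it passes the tissue mask and, if given, the S/N
    inclusion grid of *every* channel; a pixel failing any channel is invalid
    in all three output images.  Predictions with any raw value outside
    [−10, 110] % are removed (invalid).  Returns ({isomer: IonImage}, valid).
    """
    for label in ("331", "333", "341"):
        if label not in channel_images:
            raise ValueError(f"missing channel image {label!r}")
    i331 = channel_images["331"]
    i333 = channel_images["333"]
    i341 = channel_images["341"]
    if not (i331.shape == i333.shape == i341.shape):
        raise ValueError("channel images must share shape")
    ok = (
        np.asarray(mask, dtype=bool)
        & i331.mask
        & i333.mask
        & i341.mask
    )
    if inclusion is not None:
        for grid in inclusion.values():
            ok = ok & np.asarray(grid, dtype=bool)

    shape = i331.shape
    out = {iso: np.full(shape, np.nan) for iso in ("PGE2", "PGD2", "d12-PGD2")}
    valid = np.zeros(shape, dtype=bool)
    for li, px in zip(*np.nonzero(ok)):
        t = TripletAbundance(
            i331=i331.values[li, px],
            i333=i333.values[li, px],
            i341=i341.values[li, px],
        )
        if not t.defined:
            continue
        comp = predict(model, t)
        if not comp.valid:
            continue
        valid[li, px] = True
        out["PGE2"][li, px] = comp.pge2_pct
        out["PGD2"][li, px] = comp.pgd2_pct
        out["d12-PGD2"][li, px] = comp.d12pgd2_pct
    images = {
        iso: IonImage(vals, i331.pixel_size, mask=valid.copy(), units="%")
        for iso, vals in out.items()
    }
    return images, valid


def render_fraction(image: IonImage) -> np.ndarray:
    """Display transform: valid values outside [0, 100] % render as 0.

    The stored image keeps the raw valid values and validity flags; this is
    only the rendering rule for fraction images (out-of-range pixels shown
    as black/zero).
    """
    shown = np.where(image.mask, image.values, 0.0)
    shown = np.where((shown < 0) | (shown > 100), 0.0, shown)
    return shown


def roi_stats(
    fraction_images: Mapping[str, IonImage],
    roi: np.ndarray,
) -> ROIResult:
    """Mean ± SD isomer composition over the valid pixels of an ROI."""
    roi = np.asarray(roi, dtype=bool)
    stats = {}
    n_pixels = None
    for iso in ("PGE2", "PGD2", "d12-PGD2"):
        img = fraction_images[iso]
        sel = roi & img.mask & np.isfinite(img.values)
        if not sel.any():
            raise ValueError("ROI contains no valid pixels")
        vals = img.values[sel]
        stats[iso] = (float(vals.mean()), float(vals.std(ddof=0)))
        n_pixels = int(sel.sum()) if n_pixels is None else min(n_pixels, int(sel.sum()))
    return ROIResult(
        mean_pge2=stats["PGE2"][0],
        mean_pgd2=stats["PGD2"][0],
        mean_d12=stats["d12-PGD2"][0],
        sd_pge2=stats["PGE2"][1],
        sd_pgd2=stats["PGD2"][1],
        sd_d12=stats["d12-PGD2"][1],
        n_pixels=n_pixels,
    )
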