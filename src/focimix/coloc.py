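"""Voxel-level co-localization metrics for dual-channel 3-D nuclei.

Two labeled channels occupy a nucleus; the question is how much of the
nuclear volume carries signal from both.  A voxel is *co-localized* when its
intensity is strictly above the background threshold in both channels
simultaneously, and the co-localized volume is the voxel count times the
physical volume of one voxel.  The Pearson coefficient (PC, -1..1) measures
voxel-wise intensity correlation; the Mander coefficients (M_green, M_red,
0..1) measure the fraction of each channel's integrated intensity residing
in voxels where the other channel is above threshold.  A fixed-volume region
of interest placed to maximize the co-localized voxel count gives an upper
bound on local mixing.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .image_io import ImageStack
from .preprocess import (
    ThresholdSet,
    apply_threshold,
    compute_thresholds,
    gaussian_filter,
    median_filter_333,
    nuclear_mask,
)

__all__ = [
    "AnalysisConfig",
    "ColocResult",
    "RoiBox",
    "pearson",
    "manders",
    "coloc_mask",
    "coloc_volume",
    "coloc_report",
    "find_max_coloc_roi",
]


@dataclasses.dataclass(frozen=True)
class AnalysisConfig:
    """Preprocessing and measurement configuration for one analysis run.

    Parameters
    ----------
    channels
        The (green-like, red-like) channel names to analyze.
    filter
        ``"median333"`` (default), ``"gaussian"`` or ``"none"``.
    gaussian_sigma_um
        Physical sigma of the Gaussian filter (used when filter="gaussian").
    threshold_rule
        ``"sd"`` (default), ``"manual"`` or ``"none"``.
    sd_population
        Voxel population for the SD rule: "all", "nucleus" or "positive".
    manual_thresholds
        Per-channel thresholds for the manual rule.
    mander_denominator
        ``"total"`` (classic M1/M2: denominator is the full channel intensity
        over the region) or ``"thresholded"`` (both sums restricted to the
        channel's own above-threshold voxels).
    roi_volume_um3
        Physical volume of the most-co-localized cropped region.
    pc_region
        Region for the Pearson coefficient: "nucleus" (default) or "image".
    """

    channels: tuple[str, str] = ("green", "red")
    filter: str = "median333"
    gaussian_sigma_um: float = 0.08
    threshold_rule: str = "sd"
    sd_population: str = "nucleus"
    manual_thresholds: dict | None = None
    mander_denominator: str = "total"
    roi_volume_um3: float = 65.0
    pc_region: str = "nucleus"


@dataclasses.dataclass(frozen=True)
class RoiBox:
    """Axis-aligned crop maximizing the co-localized voxel count."""

    origin: tuple[int, int, int]  # (z, y, x) voxel indices
    size: tuple[int, int, int]  # voxels per axis
    volume_um3: float
    coloc_voxels: int

    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(
            slice(o, o + s) for o, s in zip(self.origin, self.size)
        )  # type: ignore[return-value]


@dataclasses.dataclass
class ColocResult:
    """Full metric row for one nucleus or cropped region."""

    region: str  # "nucleus" | "roi"
    pearson: float
    m_green: float
    m_red: float
    coloc_voxels: int
    vol_coloc_um3: float
    pct_coloc: float
    pct_green: float
    pct_red: float
    pct_occupied: float
    pct_occupied_union: float
    filter: str = ""
    threshold_rule: str = ""
    t_green: float = np.nan
    t_red: float = np.nan
    mander_denominator: str = ""
    roi: RoiBox | None = None

    def as_row(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("roi")
        d["coloc_voxels"] = self.coloc_voxels
        return d


def pearson(ch_a: np.ndarray, ch_b: np.ndarray, region: np.ndarray | None = None) -> float:
    """Sample Pearson correlation of voxel intensities over a region.

    Returns NaN (with a warning) when either channel has zero variance over
    the region — an undefined correlation is never silently reported as 0.
    """
    ch_a = np.asarray(ch_a, dtype=np.float64)
    ch_b = np.asarray(ch_b, dtype=np.float64)
    if ch_a.shape != ch_b.shape:
        raise ValueError("channel shapes differ")
    if region is not None:
        a = ch_a[region]
        b = ch_b[region]
    else:
        a = ch_a.ravel()
        b = ch_b.ravel()
    if a.size == 0:
        raise ValueError("empty region")
    da = a - a.mean()
    db = b - b.mean()
    ssa = float(np.dot(da, da))
    ssb = float(np.dot(db, db))
    if ssa == 0.0 or ssb == 0.0:
        warnings.warn("zero variance in a channel: Pearson coefficient undefined")
        return float("nan")
    return float(np.dot(da, db) / np.sqrt(ssa * ssb))


def manders(
    ch_green: np.ndarray,
    ch_red: np.ndarray,
    thresholds: ThresholdSet,
    region: np.ndarray | None = None,
    channels: tuple[str, str] = ("green", "red"),
    denominator: str = "total",
) -> tuple[float, float]:
    """Mander pair (M_green, M_red).

    ``M_green`` is the fraction of green intensity found in voxels where red
    is above its threshold; ``M_red`` symmetrically.  With
    ``denominator="total"`` the denominator is the total channel intensity
    over the region (classic M1/M2); with ``"thresholded"`` both numerator
    and denominator are restricted to the channel's own above-threshold
    voxels.  A zero denominator yields 0 with a warning.
    """
    if denominator not in ("total", "thresholded"):
        raise ValueError(f"unknown denominator convention {denominator!r}")
    g = np.asarray(ch_green, dtype=np.float64)
    r = np.asarray(ch_red, dtype=np.float64)
    if region is None:
        region = np.ones(g.shape, dtype=bool)
    t_g = thresholds[channels[0]]
    t_r = thresholds[channels[1]]
    above_g = apply_threshold(g, t_g)
    above_r = apply_threshold(r, t_r)

    def one(values, other_above, own_above):
        if denominator == "total":
            num = float(values[region & other_above].sum())
            den = float(values[region].sum())
        else:
            num = float(values[region & other_above & own_above].sum())
            den = float(values[region & own_above].sum())
        if den == 0.0:
            warnings.warn("zero Mander denominator; coefficient reported as 0")
            return 0.0
        return num / den

    return one(g, above_r, above_g), one(r, above_g, above_r)


def coloc_mask(
    ch_green: np.ndarray,
    ch_red: np.ndarray,
    thresholds: ThresholdSet,
    channels: tuple[str, str] = ("green", "red"),
) -> np.ndarray:
    """Voxels strictly above threshold in both channels simultaneously."""
    return apply_threshold(ch_green, thresholds[channels[0]]) & apply_threshold(
        ch_red, thresholds[channels[1]]
    )


def coloc_volume(mask: np.ndarray, voxel_size_um: tuple[float, float, float]) -> float:
    """Physical volume of a voxel mask: count x (pz * py * px) µm³."""
    return float(np.count_nonzero(mask)) * float(np.prod(voxel_size_um))


def _window_sums(mask: np.ndarray, size: tuple[int, int, int]) -> np.ndarray:
    """Sliding-window sums of a binary mask at every valid origin (stride 1)."""
    # 3-D summed-area table with a zero border for clean differencing
    c = np.zeros(tuple(s + 1 for s in mask.shape), dtype=np.int64)
    c[1:, 1:, 1:] = np.cumsum(np.cumsum(np.cumsum(mask, axis=0), axis=1), axis=2)
    dz, dy, dx = size
    nz, ny, nx = (mask.shape[i] - size[i] + 1 for i in range(3))
    s = (
        c[dz : dz + nz, dy : dy + ny, dx : dx + nx]
        - c[0:nz, dy : dy + ny, dx : dx + nx]
        - c[dz : dz + nz, 0:ny, dx : dx + nx]
        - c[dz : dz + nz, dy : dy + ny, 0:nx]
        + c[0:nz, 0:ny, dx : dx + nx]
        + c[0:nz, dy : dy + ny, 0:nx]
        + c[dz : dz + nz, 0:ny, 0:nx]
        - c[0:nz, 0:ny, 0:nx]
    )
    return s


def find_max_coloc_roi(
    mask: np.ndarray,
    voxel_size_um: tuple[float, float, float],
    roi_volume_um3: float = 65.0,
) -> RoiBox:
    """Place a fixed-volume box so as to maximize the co-localized voxel count.

    The box is a cube in physical units (side ``roi_volume_um3 ** (1/3)``),
    converted per axis to voxels, and slid exhaustively at stride 1.  Ties
    are broken by the lowest (z, y, x) origin in scan order; an all-empty
    mask therefore yields the origin box with count 0.
    """
    mask = np.asarray(mask, dtype=bool)
    side_um = roi_volume_um3 ** (1.0 / 3.0)
    size = tuple(
        max(1, int(round(side_um / voxel_size_um[i]))) for i in range(3)
    )
    if any(size[i] > mask.shape[i] for i in range(3)):
        raise ValueError("requested ROI exceeds the image extent")
    sums = _window_sums(mask, size)  # argmax -> first occurrence = scan order
    flat = int(np.argmax(sums))
    origin = tuple(int(v) for v in np.unravel_index(flat, sums.shape))
    vol = float(np.prod(size)) * float(np.prod(voxel_size_um))
    return RoiBox(origin=origin, size=size, volume_um3=vol, coloc_voxels=int(sums.max()))


def _percentages(
    above_g: np.ndarray,
    above_r: np.ndarray,
    both: np.ndarray,
    region: np.ndarray,
) -> tuple[float, float, float, float, float]:
    n_region = int(np.count_nonzero(region))
    pct_g = 100.0 * np.count_nonzero(above_g & region) / n_region
    pct_r = 100.0 * np.count_nonzero(above_r & region) / n_region
    pct_coloc = 100.0 * np.count_nonzero(both & region) / n_region
    pct_union = 100.0 * np.count_nonzero((above_g | above_r) & region) / n_region
    return pct_coloc, pct_g, pct_r, pct_g + pct_r, pct_union


def coloc_report(
    stack: ImageStack,
    config: AnalysisConfig = AnalysisConfig(),
    nucleus: np.ndarray | None = None,
) -> list[ColocResult]:
    """Run the full single-nucleus analysis.

    Applies the configured filter per channel, segments the nucleus (unless a
    mask is provided), computes SD-rule thresholds over the configured
    population, and returns two rows: the whole-nucleus metrics and the
    metrics inside the most-co-localized fixed-volume ROI.
    """
    if stack.is_timelapse:
        raise ValueError("coloc_report operates on single time points")
    name_g, name_r = config.channels
    raw = {name: stack.channel(name).astype(np.float64) for name in (name_g, name_r)}

    if config.filter == "median333":
        filt = {k: median_filter_333(v) for k, v in raw.items()}
    elif config.filter == "gaussian":
        filt = {
            k: gaussian_filter(v, config.gaussian_sigma_um, stack.voxel_size_um)
            for k, v in raw.items()
        }
    elif config.filter == "none":
        filt = raw
    else:
        raise ValueError(f"unknown filter {config.filter!r}")

    if nucleus is None:
        filtered_data = np.stack([filt[name_g], filt[name_r]], axis=-1)
        nucleus = nuclear_mask(filtered_data, stack.voxel_size_um)

    thresholds = compute_thresholds(
        filt,
        rule=config.threshold_rule,
        population=config.sd_population,
        nucleus=nucleus,
        manual=config.manual_thresholds,
    )
    g, r = filt[name_g], filt[name_r]
    above_g = apply_threshold(g, thresholds[name_g])
    above_r = apply_threshold(r, thresholds[name_r])
    both = above_g & above_r

    def metrics(region: np.ndarray, region_name: str, roi: RoiBox | None) -> ColocResult:
        pct_coloc, pct_g, pct_r, pct_occ, pct_union = _percentages(
            above_g, above_r, both, region
        )
        pc_region = region
        if region_name == "nucleus" and config.pc_region == "image":
            pc_region = np.ones(g.shape, dtype=bool)
        n_coloc = int(np.count_nonzero(both & region))
        mg, mr = manders(
            g,
            r,
            thresholds,
            region=region,
            channels=(name_g, name_r),
            denominator=config.mander_denominator,
        )
        return ColocResult(
            region=region_name,
            pearson=pearson(g, r, pc_region),
            m_green=mg,
            m_red=mr,
            coloc_voxels=n_coloc,
            vol_coloc_um3=n_coloc * stack.voxel_volume_um3,
            pct_coloc=pct_coloc,
            pct_green=pct_g,
            pct_red=pct_r,
            pct_occupied=pct_occ,
            pct_occupied_union=pct_union,
            filter=config.filter,
            threshold_rule=config.threshold_rule,
            t_green=thresholds[name_g],
            t_red=thresholds[name_r],
            mander_denominator=config.mander_denominator,
            roi=roi,
        )

    nucleus_row = metrics(nucleus, "nucleus", None)

    roi = find_max_coloc_roi(
        both & nucleus, stack.voxel_size_um, config.roi_volume_um3
    )
    box_mask = np.zeros(g.shape, dtype=bool)
    box_mask[roi.slices()] = True
    roi_row = metrics(box_mask, "roi", roi)
    return [nucleus_row, roi_row]
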