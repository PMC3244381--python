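"""Synthetic two-channel nuclei with known ground-truth chromatin mixing.

The generator emulates a nucleus whose DNA was pulse-labeled in two
consecutive cell cycles: after random mitotic segregation each chromosome
territory carries foci of a single color, territories are spatially
segregated, and genuine two-channel mixing is confined to territory
interfaces.  The model is deliberately geometric, not polymeric:

* the nucleus is a voxelized ellipsoid (default volume ~1950 µm³ at the
  anisotropic confocal pitch 0.34 x 0.8 x 0.8 µm in Z/Y/X);
* territories are a nearest-seed (Voronoi) partition of the ellipsoid in
  physical coordinates, each labeled green, red or left unlabeled;
* DNA foci (~0.41 µm diameter) are Gaussian intensity blobs packed into
  dense sub-clusters scattered through their territory, so labeled signal
  forms contiguous chromatin patches (as it must at a 0.8 µm lateral pitch,
  where single foci are unresolved) rather than isolated voxels;
* a fraction ``f_mix`` of the foci lying within one focus diameter of a
  territory carrying the other label is displaced just across the interface
  — the ground truth for inter-chromosomal mixing;
* ``dispersion_factor`` (>=1) both widens the sub-cluster spread (letting
  foci stray across territory borders) and swells the rendered focus size,
  emulating the "swollen and dispersed" foci induced by histone-deacetylase
  inhibition (TSA);
* detector noise is additive Gaussian; electronic noise is isolated voxels
  at the maximum of the bit depth (which a 3x3x3 median filter removes);
* a faint uniform nucleoplasmic baseline inside the ellipsoid stands in for
  the diffuse label/counterstain signal that makes nuclear segmentation
  possible in real images.

All randomness flows from one integer seed through fixed per-stage
sub-streams (geometry, foci, noise, motion), so identical specs give
bit-identical stacks and adding time-lapse frames never perturbs geometry.
"""

from __future__ import annotations

import dataclasses
import math
import warnings

import numpy as np
import pandas as pd
from scipy import ndimage

from .image_io import ImageStack

__all__ = [
    "NucleusSpec",
    "GroundTruth",
    "partition_territories",
    "place_and_render",
    "generate_timelapse",
]

_FWHM = 2.0 * math.sqrt(2.0 * math.log(2.0))  # sigma -> full width at half max

# sub-stream indices off the master seed
_GEOMETRY, _FOCI, _NOISE, _MOTION = 0, 1, 2, 3


@dataclasses.dataclass(frozen=True)
class NucleusSpec:
    """All generator parameters for one synthetic nucleus.

    Parameters
    ----------
    semi_axes_um
        Ellipsoid semi-axes (z, y, x) in µm.  The default gives a nuclear
        volume of ~1945 µm³.
    voxel_size_um
        Voxel pitch (z, y, x) in µm.
    n_territories
        Number of Voronoi territories (>= 2, so an interface exists).
    channel_assignment
        ``"alternate"`` (territories cycle green/red) or an explicit tuple of
        per-territory channel names drawn from {"green", "red", "none"}.
    foci_per_territory
        Foci rendered into each labeled territory.
    focus_diameter_um
        Full width at half maximum of a rendered focus.
    f_mix
        Fraction of interface foci (those within one focus diameter of a
        territory carrying the other label) displaced across the interface.
    dispersion_factor
        >= 1; multiplies the sub-cluster spread and the rendered focus
        diameter and, when > 1, allows foci to land outside their territory
        (TSA analog).
    clusters_per_territory
        Number of sub-cluster anchor points scattered uniformly through each
        territory; foci pack tightly around them.
    cluster_sigma_um
        Gaussian spread of foci about their sub-cluster anchor.
    min_focus_separation_um
        Minimum distance between same-channel foci (0 disables).  Used by
        the time-lapse study condition, where only foci that can be
        followed without ambiguity are useful.
    amplitude
        Peak intensity of one focus (before overlap and clipping).
    nuclear_baseline
        Uniform diffuse intensity added inside the nucleus in each channel.
    noise_sd
        Additive Gaussian detector noise (intensity units).
    impulse_prob
        Per-voxel probability of an isolated maximal-intensity impulse.
    bit_depth
        Dynamic range of the rendered stack.
    seed
        Master seed for all sub-streams.
    """

    semi_axes_um: tuple[float, float, float] = (4.3, 9.0, 12.0)
    voxel_size_um: tuple[float, float, float] = (0.34, 0.8, 0.8)
    n_territories: int = 8
    channel_assignment: str | tuple[str, ...] = "alternate"
    foci_per_territory: int = 500
    focus_diameter_um: float = 0.41
    f_mix: float = 0.1
    dispersion_factor: float = 1.0
    clusters_per_territory: int = 8
    cluster_sigma_um: float = 0.55
    min_focus_separation_um: float = 0.0
    amplitude: float = 160.0
    nuclear_baseline: float = 6.0
    noise_sd: float = 6.0
    impulse_prob: float = 0.001
    bit_depth: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.semi_axes_um):
            raise ValueError("semi-axes must be positive")
        if any(p <= 0 for p in self.voxel_size_um):
            raise ValueError("voxel pitches must be positive")
        if not 0.0 <= self.f_mix <= 1.0:
            raise ValueError("f_mix must lie in [0, 1]")
        if self.dispersion_factor < 1.0:
            raise ValueError("dispersion_factor must be >= 1")
        if self.focus_diameter_um <= 0:
            raise ValueError("focus diameter must be positive")

    @property
    def max_value(self) -> int:
        return 2**self.bit_depth - 1

    def territory_channels(self) -> tuple[str, ...]:
        if isinstance(self.channel_assignment, str):
            if self.channel_assignment != "alternate":
                raise ValueError(
                    f"unknown assignment rule {self.channel_assignment!r}"
                )
            return tuple(
                ("green", "red")[i % 2] for i in range(self.n_territories)
            )
        assignment = tuple(self.channel_assignment)
        if len(assignment) != self.n_territories:
            raise ValueError("channel_assignment length != n_territories")
        if any(c not in ("green", "red", "none") for c in assignment):
            raise ValueError("channels must be 'green', 'red' or 'none'")
        return assignment

    def rng(self, stream: int, extra: int | None = None) -> np.random.Generator:
        key = [self.seed, stream] if extra is None else [self.seed, stream, extra]
        return np.random.default_rng(key)


@dataclasses.dataclass
class GroundTruth:
    """Known truth for one generated nucleus.

    ``label_map`` is an integer territory id per voxel (0 outside the
    nucleus); ``foci`` is one record per focus with its physical center,
    channel and territory; ``mixed_mask`` marks voxels whose *noise-free*
    rendered intensity is above the SD-rule threshold in both channels, and
    ``mixing_percent`` is that mask as a percentage of nuclear voxels.
    """

    label_map: np.ndarray
    nucleus_mask: np.ndarray
    foci: pd.DataFrame | None = None
    mixed_mask: np.ndarray | None = None
    mixing_percent: float | None = None
    nuclear_volume_um3: float | None = None


# ---------------------------------------------------------------------------
# geometry


def _grid_coords(
    spec: NucleusSpec,
) -> tuple[tuple[int, ...], list[np.ndarray], np.ndarray]:
    """Grid shape, per-axis voxel-center coordinates and the nucleus center.

    Coordinates follow the package convention: 0-based and voxel-centered,
    i.e. voxel ``i`` along an axis is at ``i * pitch`` µm; the ellipsoid is
    centered mid-grid.
    """
    margin = 2
    shape = tuple(
        int(math.ceil(2.0 * a / p)) + 2 * margin
        for a, p in zip(spec.semi_axes_um, spec.voxel_size_um)
    )
    coords = [np.arange(n) * p for n, p in zip(shape, spec.voxel_size_um)]
    center = np.array(
        [(n - 1) / 2.0 * p for n, p in zip(shape, spec.voxel_size_um)]
    )
    return shape, coords, center


def partition_territories(spec: NucleusSpec) -> GroundTruth:
    """Voronoi partition of the voxelized ellipsoid among uniform seeds.

    Seed points are drawn uniformly inside the ellipsoid (in physical
    coordinates) from the geometry sub-stream; every nuclear voxel is
    assigned to its nearest seed.  Deterministic for a fixed spec.
    """
    if spec.n_territories < 2:
        raise ValueError("at least 2 territories are required (no interface otherwise)")
    shape, coords, center = _grid_coords(spec)
    zz = ((coords[0] - center[0]) / spec.semi_axes_um[0]) ** 2
    yy = ((coords[1] - center[1]) / spec.semi_axes_um[1]) ** 2
    xx = ((coords[2] - center[2]) / spec.semi_axes_um[2]) ** 2
    inside = zz[:, None, None] + yy[None, :, None] + xx[None, None, :] <= 1.0

    rng = spec.rng(_GEOMETRY)
    seeds = []
    semi = np.asarray(spec.semi_axes_um)
    while len(seeds) < spec.n_territories:
        p = rng.uniform(-semi, semi)
        if float(np.sum((p / semi) ** 2)) <= 1.0:
            seeds.append(center + p)
    seeds = np.asarray(seeds)  # (k, 3) µm

    vox = np.stack(np.nonzero(inside), axis=1)  # (n, 3)
    pos = np.stack([coords[ax][vox[:, ax]] for ax in range(3)], axis=1)
    d2 = ((pos[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2)
    labels = np.zeros(shape, dtype=np.int32)
    labels[tuple(vox.T)] = np.argmin(d2, axis=1) + 1

    vol = float(np.count_nonzero(inside)) * float(np.prod(spec.voxel_size_um))
    return GroundTruth(label_map=labels, nucleus_mask=inside, nuclear_volume_um3=vol)


# ---------------------------------------------------------------------------
# foci placement


def _territory_info(spec: NucleusSpec, labels: np.ndarray):
    """Centroid (µm), voxel list and effective radius per territory."""
    _, coords, _center = _grid_coords(spec)
    info = {}
    vox_vol = float(np.prod(spec.voxel_size_um))
    for t in range(1, spec.n_territories + 1):
        vox = np.stack(np.nonzero(labels == t), axis=1)
        if vox.size == 0:
            continue
        pos = np.stack([coords[ax][vox[:, ax]] for ax in range(3)], axis=1)
        centroid = pos.mean(axis=0)
        r_eff = (3.0 * len(vox) * vox_vol / (4.0 * math.pi)) ** (1.0 / 3.0)
        info[t] = (centroid, vox, r_eff)
    return info, coords


def _pos_to_voxel(pos: np.ndarray, coords: list[np.ndarray], shape) -> tuple[int, int, int]:
    return tuple(
        int(np.clip(round((pos[ax] - coords[ax][0]) / (coords[ax][1] - coords[ax][0])), 0, shape[ax] - 1))
        for ax in range(3)
    )


def _sample_foci(spec: NucleusSpec, labels: np.ndarray, rng: np.random.Generator) -> pd.DataFrame:
    """Sample focus centers in dense sub-clusters, then apply the
    interface-mixing displacement rule."""
    shape = labels.shape
    info, coords = _territory_info(spec, labels)
    channels = spec.territory_channels()
    nucleus = labels > 0
    channel_of_territory = dict(zip(sorted(info), channels))

    sigma = spec.cluster_sigma_um * spec.dispersion_factor
    confined = spec.dispersion_factor <= 1.0

    records = []
    fid = 0
    for t, channel in zip(sorted(info), channels):
        if channel == "none":
            continue
        _, vox, _ = info[t]
        # sub-cluster anchors scattered uniformly through the territory
        anchor_vox = vox[rng.choice(len(vox), size=spec.clusters_per_territory)]
        anchors = np.stack(
            [coords[ax][anchor_vox[:, ax]] for ax in range(3)], axis=1
        )
        channel_positions = [
            np.array([r["z_um"], r["y_um"], r["x_um"]])
            for r in records
            if r["channel"] == channel
        ]
        for _ in range(spec.foci_per_territory):
            anchor = anchors[rng.integers(len(anchors))]
            placed = None
            for _try in range(200):
                p = anchor + rng.normal(size=3) * sigma
                v = _pos_to_voxel(p, coords, shape)
                if not nucleus[v]:
                    continue
                if confined and labels[v] != t:
                    continue
                if spec.min_focus_separation_um > 0 and any(
                    np.linalg.norm(p - q) < spec.min_focus_separation_um
                    for q in channel_positions
                ):
                    continue
                placed = (p, v)
                break
            if placed is None:  # tight corner: fall back to the anchor voxel
                iv = anchor_vox[rng.integers(len(anchor_vox))]
                p = np.array([coords[ax][iv[ax]] for ax in range(3)])
                placed = (p, tuple(iv))
            p, v = placed
            records.append(
                dict(
                    focus_id=fid,
                    channel=channel,
                    territory=t,
                    host_territory=int(labels[v]),
                    z_um=p[0],
                    y_um=p[1],
                    x_um=p[2],
                    interface=False,
                    displaced=False,
                )
            )
            channel_positions.append(np.asarray(p, dtype=float))
            fid += 1

    foci = pd.DataFrame.from_records(records)

    # interface displacement: a focus lying within one focus diameter of a
    # territory carrying the other label may be relocated into the neighbor's
    # occupied space — next to its nearest other-channel focus, so the two
    # labels genuinely share voxels (chromatin of the two domains mixes where
    # their surfaces touch, not in empty inter-chromatin space)
    if len(foci) and spec.f_mix > 0:
        from scipy.spatial import cKDTree

        edt = {}
        for channel in ("green", "red"):
            other = "red" if channel == "green" else "green"
            other_mask = np.isin(
                labels,
                [t for t, c in channel_of_territory.items() if c == other],
            )
            if other_mask.any():
                edt[channel] = ndimage.distance_transform_edt(
                    ~other_mask, sampling=spec.voxel_size_um
                )
        pos_all = foci[["z_um", "y_um", "x_um"]].to_numpy(dtype=float)
        trees = {
            ch: cKDTree(pos_all[(foci["channel"] == ch).to_numpy()])
            for ch in ("green", "red")
            if (foci["channel"] == ch).any()
        }
        index_of = {
            ch: foci.index[(foci["channel"] == ch).to_numpy()].to_numpy()
            for ch in trees
        }
        for i in foci.index:
            channel = foci.at[i, "channel"]
            other = "red" if channel == "green" else "green"
            if channel not in edt or other not in trees:
                continue
            p = foci.loc[i, ["z_um", "y_um", "x_um"]].to_numpy(dtype=float)
            v = _pos_to_voxel(p, coords, shape)
            if edt[channel][v] <= spec.focus_diameter_um:
                foci.at[i, "interface"] = True
                if rng.random() < spec.f_mix:
                    # land on one of the nearest other-channel foci (picked
                    # at random so displaced foci tile the touching surface
                    # instead of piling onto a single partner)
                    k = min(12, trees[other].n)
                    _, js = trees[other].query(p, k=k)
                    j = int(np.atleast_1d(js)[rng.integers(k)])
                    target = pos_all[index_of[other][j]]
                    newp = target + rng.normal(
                        0.0, spec.focus_diameter_um / 4.0, size=3
                    )
                    vt = _pos_to_voxel(newp, coords, shape)
                    foci.loc[i, ["z_um", "y_um", "x_um"]] = newp
                    foci.at[i, "displaced"] = True
                    foci.at[i, "host_territory"] = int(labels[vt])
    return foci


# ---------------------------------------------------------------------------
# rendering


def _render_clean(
    spec: NucleusSpec,
    foci: pd.DataFrame,
    nucleus: np.ndarray,
    shape,
    coords,
) -> np.ndarray:
    """Noise-free (Z,Y,X,2) float rendering: Gaussian blobs + baseline."""
    from scipy.special import ndtr

    clean = np.zeros(shape + (2,), dtype=np.float64)
    ch_index = {"green": 0, "red": 1}
    # TSA-analog dispersion swells the rendered foci as well as scattering
    # them; the swell grows as the square root so the occupied volume does
    # not explode with the scatter
    diameter = spec.focus_diameter_um * math.sqrt(spec.dispersion_factor)
    sigma_um = diameter / _FWHM
    sigma_vox = [sigma_um / p for p in spec.voxel_size_um]
    if diameter < min(spec.voxel_size_um):
        warnings.warn(
            "focus diameter below every voxel pitch; foci render as single voxels"
        )
    half = [max(1, int(math.ceil(3.5 * s)) + 1) for s in sigma_vox]
    pitches = spec.voxel_size_um

    # each voxel receives the Gaussian flux integrated over its extent
    # (voxels bin photons; a focus keeps its total intensity regardless of
    # where its center falls relative to the voxel grid)
    for rec in foci.itertuples():
        ci = ch_index[rec.channel]
        center = np.array([rec.z_um, rec.y_um, rec.x_um])
        v = _pos_to_voxel(center, coords, shape)
        sl = tuple(
            slice(max(0, v[ax] - half[ax]), min(shape[ax], v[ax] + half[ax] + 1))
            for ax in range(3)
        )
        fracs = []
        for ax in range(3):
            centers = coords[ax][sl[ax]]
            lo = (centers - pitches[ax] / 2.0 - center[ax]) / sigma_um
            hi = (centers + pitches[ax] / 2.0 - center[ax]) / sigma_um
            fracs.append(ndtr(hi) - ndtr(lo))
        blob = (
            fracs[0][:, None, None]
            * fracs[1][None, :, None]
            * fracs[2][None, None, :]
        )
        clean[sl + (ci,)] += spec.amplitude * blob

    clean[nucleus] += spec.nuclear_baseline
    return clean


def _true_mixed_mask(
    spec: NucleusSpec, clean: np.ndarray, nucleus: np.ndarray
) -> tuple[np.ndarray, float]:
    """Ground-truth mixing: both noise-free channels above their SD-rule
    threshold (computed over nuclear voxels) in the same voxel.

    The clean rendering is clipped to the declared bit depth first — truth
    refers to what the detector records, not to unbounded model intensity.
    """
    clipped = np.clip(clean, 0, spec.max_value)
    t_g = float(np.std(clipped[..., 0][nucleus]))
    t_r = float(np.std(clipped[..., 1][nucleus]))
    mixed = (clipped[..., 0] > t_g) & (clipped[..., 1] > t_r) & nucleus
    pct = 100.0 * np.count_nonzero(mixed) / np.count_nonzero(nucleus)
    return mixed, pct


def _add_noise(
    spec: NucleusSpec, clean: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    noisy = clean.copy()
    if spec.noise_sd > 0:
        noisy = noisy + rng.normal(0.0, spec.noise_sd, size=clean.shape)
    if spec.impulse_prob > 0:
        impulses = rng.random(clean.shape) < spec.impulse_prob
        noisy[impulses] = spec.max_value
    noisy = np.clip(np.rint(noisy), 0, spec.max_value)
    dtype = np.uint8 if spec.bit_depth <= 8 else np.uint16
    return noisy.astype(dtype)


def place_and_render(
    spec: NucleusSpec, partition: GroundTruth
) -> tuple[ImageStack, GroundTruth]:
    """Place foci into a partitioned nucleus and render the two channels.

    Returns the noisy :class:`ImageStack` together with the completed
    :class:`GroundTruth` (focus table, true mixed mask, mixing percent).
    """
    shape, coords, _center = _grid_coords(spec)
    labels = partition.label_map
    nucleus = partition.nucleus_mask
    rng = spec.rng(_FOCI)
    foci = _sample_foci(spec, labels, rng)
    clean = _render_clean(spec, foci, nucleus, shape, coords)
    mixed, pct = _true_mixed_mask(spec, clean, nucleus)
    noisy = _add_noise(spec, clean, spec.rng(_NOISE))
    stack = ImageStack(
        data=noisy,
        voxel_size_um=spec.voxel_size_um,
        channel_names=("green", "red"),
        bit_depth=spec.bit_depth,
    )
    gt = GroundTruth(
        label_map=labels,
        nucleus_mask=nucleus,
        foci=foci,
        mixed_mask=mixed,
        mixing_percent=pct,
        nuclear_volume_um3=partition.nuclear_volume_um3,
    )
    return stack, gt


def generate_nucleus(spec: NucleusSpec) -> tuple[ImageStack, GroundTruth]:
    """Convenience: partition + place + render in one call."""
    return place_and_render(spec, partition_territories(spec))


def timelapse_spec(seed: int = 0, **overrides) -> NucleusSpec:
    """Study condition for foci-mobility time lapses.

    Mobility analysis needs individually resolvable foci, so this condition
    renders far fewer, well-separated foci than the mixing condition (live
    imaging in the source experiments likewise tracked only isolated foci
    that could be followed without ambiguity).  Two green (early) and two
    red (late) territories carry 8 foci each, spread widely; mixing is off.
    """
    params = dict(
        n_territories=4,
        foci_per_territory=8,
        clusters_per_territory=2,
        cluster_sigma_um=2.5,
        min_focus_separation_um=1.8,
        f_mix=0.0,
        seed=seed,
    )
    params.update(overrides)
    return NucleusSpec(**params)


# ---------------------------------------------------------------------------
# time lapse


def generate_timelapse(
    spec: NucleusSpec,
    n_frames: int = 4,
    frame_interval_min: float = 15.0,
    step_sd_early: float = 0.3,
    step_sd_late: float = 0.1,
    anchor_drift_sd: float = 0.05,
) -> tuple[ImageStack, pd.DataFrame]:
    """Render a 4-D time lapse of foci performing confined random walks.

    Green-channel foci are the *early* (euchromatic) class; red-channel foci
    are the *late* (heterochromatic) class.  Each focus performs a reflected
    Gaussian random walk confined to its territory with per-axis, per-frame
    step sd given by its class (the default early value of 0.3 µm gives a
    mean 3-D step of ~0.48 µm per 15-min interval).  Late foci of one
    territory additionally share a slowly drifting cluster anchor, so they
    move coherently and can serve as registration landmarks.

    Returns the (T,Z,Y,X,C) stack and the ground-truth track table
    (focus_id, cls, channel, frame, z/y/x in µm).
    """
    if n_frames < 2:
        raise ValueError("a time lapse needs at least 2 frames")
    if step_sd_early < 0 or step_sd_late < 0:
        raise ValueError("step standard deviations must be non-negative")

    partition = partition_territories(spec)
    shape, coords, _center = _grid_coords(spec)
    labels = partition.label_map
    nucleus = partition.nucleus_mask
    foci0 = _sample_foci(spec, labels, spec.rng(_FOCI))
    motion = spec.rng(_MOTION)
    noise = spec.rng(_NOISE)

    cls_of = {"green": "early", "red": "late"}
    step_sd = {"early": step_sd_early, "late": step_sd_late}

    positions = foci0[["z_um", "y_um", "x_um"]].to_numpy(dtype=float)
    channels = foci0["channel"].to_numpy()
    territories = foci0["host_territory"].to_numpy()
    late_territories = sorted(set(territories[channels == "red"]))

    def inside_territory(p: np.ndarray, t: int) -> bool:
        v = _pos_to_voxel(p, coords, shape)
        return bool(labels[v] == t)

    frames_data = []
    track_rows = []

    def record(frame: int) -> None:
        for i in range(len(positions)):
            track_rows.append(
                dict(
                    focus_id=int(foci0["focus_id"].iloc[i]),
                    cls=cls_of[channels[i]],
                    channel=channels[i],
                    frame=frame,
                    z_um=positions[i, 0],
                    y_um=positions[i, 1],
                    x_um=positions[i, 2],
                )
            )

    def render_current() -> np.ndarray:
        table = foci0.copy()
        table[["z_um", "y_um", "x_um"]] = positions
        clean = _render_clean(spec, table, nucleus, shape, coords)
        return _add_noise(spec, clean, noise)

    record(0)
    frames_data.append(render_current())

    for frame in range(1, n_frames):
        anchor_steps = {
            t: motion.normal(0.0, anchor_drift_sd, size=3) for t in late_territories
        }
        for i in range(len(positions)):
            cls = cls_of[channels[i]]
            sd = step_sd[cls]
            base = positions[i].copy()
            if cls == "late":
                base = base + anchor_steps[territories[i]]
                if not inside_territory(base, territories[i]):
                    base = positions[i].copy()
            new = base
            if sd > 0:
                for _try in range(20):
                    candidate = base + motion.normal(0.0, sd, size=3)
                    if inside_territory(candidate, territories[i]):
                        new = candidate
                        break
                else:
                    new = base
            positions[i] = new
        record(frame)
        frames_data.append(render_current())

    stack = ImageStack(
        data=np.stack(frames_data, axis=0),
        voxel_size_um=spec.voxel_size_um,
        channel_names=("green", "red"),
        bit_depth=spec.bit_depth,
        frame_interval_min=frame_interval_min,
    )
    return stack, pd.DataFrame.from_records(track_rows)
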