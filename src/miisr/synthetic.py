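"""Ground-truth scene generators and SMLM sampling-artefact models.

Everything the analysis suite claims can be exercised without microscope
data: two-channel fluorophore pair fields at fixed separations, clustered
molecule fields, the two characteristic SMLM sampling artefacts
(undersampling = missed fluorophores, oversampling = repeat detections of
one fluorophore), and a frame-wise acquisition simulator with an
autocorrelation-based criterion for where to stop image reconstruction.

All generators are driven by an explicit seed (or a ``numpy`` Generator)
and are bit-reproducible.  Localization error is modelled as isotropic
normal jitter whose full width at half maximum is half the nominal
microscope precision — FWHM = 0.5·precision, σ = FWHM / 2√(2 ln 2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .roi import RasterImage, RegionOfInterest, rasterize
from .tables import LocalizationTable

__all__ = [
    "FWHM_TO_SIGMA",
    "SyntheticScene",
    "AcquisitionSeries",
    "ReconstructionResult",
    "jitter_positions",
    "make_pair_field",
    "make_clustered_scene",
    "apply_undersampling",
    "apply_oversampling",
    "simulate_acquisition",
    "reconstruct_with_autocorrelation",
]

#: FWHM = 2·sqrt(2·ln 2) · σ for a normal distribution.
FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


def _sigma_from_precision(precision: float) -> float:
    """Jitter σ in nm for a nominal microscope precision in nm."""
    return 0.5 * precision / FWHM_TO_SIGMA


@dataclass
class SyntheticScene:
    """A generated multi-channel field with per-molecule ground truth.

    ``truth[channel_id]`` assigns each molecule its cluster id or pair id,
    with −1 marking noise/unpaired molecules.
    """

    channels: dict[str, LocalizationTable]
    truth: dict[str, np.ndarray]
    params: dict
    seed: Optional[int] = None
    region: Optional[RegionOfInterest] = None

    def channel(self, channel_id: str) -> LocalizationTable:
        return self.channels[channel_id]


def jitter_positions(table: LocalizationTable, precision: float, rng
                     ) -> LocalizationTable:
    """Isotropic normal localization jitter with FWHM = 0.5·precision."""
    rng = np.random.default_rng(rng)
    sigma = _sigma_from_precision(precision)
    xy = table.xy + rng.normal(0.0, sigma, (table.n, 2))
    out = table.with_coords(xy)
    if out.precision is None:
        out.precision = np.full(out.n, float(precision))
    return out


def make_pair_field(extent: float = 8500.0, n_pairs: int = 5000,
                    separation: float = 10.2,
                    unpaired_b_fraction: float = 0.0,
                    precision: Optional[float] = None,
                    seed=None) -> SyntheticScene:
    """Two-channel field of molecule pairs at an exact separation.

    Emulates fields of annealed dye-labelled DNA duplexes: ``n_pairs``
    channel-A molecules uniform over an ``extent`` × ``extent`` nm square,
    each with a channel-B partner placed at exactly ``separation`` nm in a
    uniform random direction.  ``unpaired_b_fraction`` adds that fraction
    of extra unpaired B molecules uniformly (emulating un-annealed excess
    of one species).  When ``precision`` is given, both channels are
    jittered with FWHM = 0.5·precision noise and carry that precision
    value per molecule.

    The default extent gives a same-channel mean spacing of ~60 nm at
    n_pairs = 5000, matching sparsely deposited oligo fields.
    """
    if separation < 0:
        raise ValueError("separation must be >= 0")
    if unpaired_b_fraction < 0:
        raise ValueError("unpaired_b_fraction must be >= 0")
    rng = np.random.default_rng(seed)
    a_xy = rng.uniform(0.0, extent, (n_pairs, 2))
    theta = rng.uniform(0.0, 2.0 * np.pi, n_pairs)
    b_xy = a_xy + separation * np.column_stack([np.cos(theta), np.sin(theta)])
    n_unpaired = int(round(unpaired_b_fraction * n_pairs))
    if n_unpaired:
        b_xy = np.vstack([b_xy, rng.uniform(0.0, extent, (n_unpaired, 2))])
    a = LocalizationTable(x=a_xy[:, 0], y=a_xy[:, 1], channel_id="A")
    b = LocalizationTable(x=b_xy[:, 0], y=b_xy[:, 1], channel_id="B")
    truth_a = np.arange(n_pairs)
    truth_b = np.concatenate([np.arange(n_pairs),
                              np.full(n_unpaired, -1, dtype=int)])
    if precision is not None:
        a = jitter_positions(a, precision, rng)
        b = jitter_positions(b, precision, rng)
    return SyntheticScene(
        channels={"A": a, "B": b},
        truth={"A": truth_a, "B": truth_b},
        params={"extent": extent, "n_pairs": n_pairs,
                "separation": separation,
                "unpaired_b_fraction": unpaired_b_fraction,
                "precision": precision},
        seed=seed if isinstance(seed, (int, np.integer)) else None,
        region=RegionOfInterest.rectangle(0, 0, extent, extent),
    )


def make_clustered_scene(extent: float = 5000.0, n_clusters: int = 200,
                         molecules_per_cluster: int = 100,
                         size_jitter: int = 10,
                         cluster_radius: float = 75.0,
                         radius_jitter: float = 37.5,
                         noise_fraction: float = 0.10,
                         n_channels: int = 1,
                         jitter_model: str = "uniform",
                         seed=None) -> SyntheticScene:
    """Field of circular molecular clusters plus unclustered noise.

    Cluster centres are uniform over the square field.  With the default
    ``uniform`` jitter model, each cluster's molecule count is
    ``(molecules_per_cluster + size_jitter) − U{0..2·size_jitter}`` and its
    radius ``(cluster_radius + radius_jitter) − U[0, 2·radius_jitter]`` —
    i.e. mean ± half-range.  ``gaussian`` draws both from normals with the
    half-range as SD instead.  Molecules are placed by a uniform random
    angle and a uniform random radius (denser toward cluster centres).
    Noise molecules — ``noise_fraction`` × the clustered count — are
    uniform over the field.

    ``n_channels = 2`` generates two independent molecule populations
    co-clustered in the *same* clusters, for cross-channel statistics.

    Defaults are the acquisition-modelling conditions (5000×5000 nm, 200
    clusters of 100 ± 10 molecules, radii 75 ± 37.5 nm, 10% noise); the
    pre-clustered co-clustering variant uses 50 clusters of fixed 50 nm
    radius with 100 molecules each.
    """
    rng = np.random.default_rng(seed)
    centres = rng.uniform(0.0, extent, (n_clusters, 2))
    channels: dict[str, LocalizationTable] = {}
    truth: dict[str, np.ndarray] = {}
    for ch in range(n_channels):
        xs, ys, ids = [], [], []
        for ci in range(n_clusters):
            if jitter_model == "uniform":
                size = (molecules_per_cluster + size_jitter
                        - rng.integers(0, 2 * size_jitter + 1)) \
                    if size_jitter else molecules_per_cluster
                radius = (cluster_radius + radius_jitter
                          - rng.uniform(0, 2 * radius_jitter)) \
                    if radius_jitter else cluster_radius
            elif jitter_model == "gaussian":
                size = max(1, int(round(rng.normal(molecules_per_cluster,
                                                   size_jitter))))
                radius = max(1.0, rng.normal(cluster_radius, radius_jitter))
            else:
                raise ValueError("jitter_model must be uniform or gaussian")
            ang = rng.uniform(0.0, 2.0 * np.pi, size)
            rad = rng.uniform(0.0, radius, size)
            xs.append(centres[ci, 0] + rad * np.cos(ang))
            ys.append(centres[ci, 1] + rad * np.sin(ang))
            ids.append(np.full(size, ci, dtype=int))
        x = np.concatenate(xs)
        y = np.concatenate(ys)
        ids = np.concatenate(ids)
        n_noise = int(round(noise_fraction * x.size))
        if n_noise:
            x = np.concatenate([x, rng.uniform(0.0, extent, n_noise)])
            y = np.concatenate([y, rng.uniform(0.0, extent, n_noise)])
            ids = np.concatenate([ids, np.full(n_noise, -1, dtype=int)])
        cid = chr(ord("A") + ch)
        channels[cid] = LocalizationTable(x=x, y=y, channel_id=cid)
        truth[cid] = ids
    return SyntheticScene(
        channels=channels, truth=truth,
        params={"extent": extent, "n_clusters": n_clusters,
                "molecules_per_cluster": molecules_per_cluster,
                "size_jitter": size_jitter,
                "cluster_radius": cluster_radius,
                "radius_jitter": radius_jitter,
                "noise_fraction": noise_fraction,
                "centres": centres,
                "jitter_model": jitter_model},
        seed=seed if isinstance(seed, (int, np.integer)) else None,
        region=RegionOfInterest.rectangle(0, 0, extent, extent),
    )


def apply_undersampling(table: LocalizationTable, fraction_deleted: float,
                        cdc: float, seed=None) -> LocalizationTable:
    """Model missed fluorophores: delete molecules plus their repeats.

    A uniform random ``fraction_deleted`` of the molecules is selected;
    each selected molecule is removed together with every same-channel
    molecule within ``cdc`` nm of it (any repeat detections of the same
    fluorophore), so the removal count can exceed n·fraction.
    """
    if not 0 <= fraction_deleted <= 1:
        raise ValueError("fraction_deleted must be in [0, 1]")
    if fraction_deleted == 0:
        return table.subset(np.arange(table.n))
    rng = np.random.default_rng(seed)
    n = table.n
    n_sel = int(round(fraction_deleted * n))
    selected = rng.choice(n, size=n_sel, replace=False)
    tree = cKDTree(table.coords)
    remove = np.zeros(n, dtype=bool)
    remove[selected] = True
    for nb in tree.query_ball_point(table.coords[selected], cdc):
        remove[nb] = True
    return table.subset(~remove)


def apply_oversampling(table: LocalizationTable, fraction_duplicated: float,
                       cdc_diameter: float = 21.27, seed=None
                       ) -> LocalizationTable:
    """Model repeat detections: duplicate molecules with resampled positions.

    A uniform random ``fraction_duplicated`` of the molecules is selected
    (with replacement when the fraction exceeds 1) and duplicated, each
    duplicate's position redrawn uniformly within a disc of diameter
    ``cdc_diameter`` centred on its parent.  The default diameter is the
    two-colour CDC of a typical ~20 nm-precision acquisition.
    """
    if fraction_duplicated < 0:
        raise ValueError("fraction_duplicated must be >= 0")
    rng = np.random.default_rng(seed)
    n = table.n
    n_dup = int(round(fraction_duplicated * n))
    if n_dup == 0:
        return table.subset(np.arange(n))
    parents = rng.choice(n, size=n_dup, replace=n_dup > n)
    # uniform in a disc of radius cdc_diameter / 2
    u = rng.uniform(0.0, 1.0, n_dup)
    theta = rng.uniform(0.0, 2.0 * np.pi, n_dup)
    rad = (cdc_diameter / 2.0) * np.sqrt(u)
    offsets = np.column_stack([rad * np.cos(theta), rad * np.sin(theta)])
    dup = table.subset(parents)
    dup = dup.with_coords(dup.xy + offsets)
    return LocalizationTable(
        x=np.concatenate([table.x, dup.x]),
        y=np.concatenate([table.y, dup.y]),
        z=np.concatenate([table.z, dup.z]),
        photons=None if table.photons is None
        else np.concatenate([table.photons, dup.photons]),
        precision=None if table.precision is None
        else np.concatenate([table.precision, dup.precision]),
        channel_id=table.channel_id,
        has_z=table.has_z,
    )


@dataclass
class AcquisitionSeries:
    """Frame-wise detections from a simulated SMLM acquisition.

    Flat arrays over all detections: ``frame`` (0-based frame index),
    ``molecule`` (ground-truth molecule index) and jittered ``x, y``
    positions in nm.
    """

    frame: np.ndarray
    molecule: np.ndarray
    x: np.ndarray
    y: np.ndarray
    n_frames: int
    precision: float
    active_range: tuple[int, int]
    region: Optional[RegionOfInterest] = None

    @property
    def n_detections(self) -> int:
        return self.frame.size

    def detections_up_to(self, frame: int) -> np.ndarray:
        """(m, 2) positions of all detections in frames [0, frame]."""
        sel = self.frame <= frame
        return np.column_stack([self.x[sel], self.y[sel]])


def simulate_acquisition(table: LocalizationTable, n_frames: int = 10000,
                         active_range: tuple[int, int] = (10, 20),
                         precision: float = 20.0, seed=None,
                         region: Optional[RegionOfInterest] = None
                         ) -> AcquisitionSeries:
    """Simulate stochastic frame-wise imaging of a ground-truth field.

    Each frame activates a uniform random subset of the molecules, of size
    drawn uniformly from ``active_range`` (inclusive); each detection is
    the molecule's true position jittered by isotropic normal noise with
    FWHM = 0.5·precision.  Defaults are 10,000 frames with 10–20 active
    molecules per frame at 20 nm precision.
    """
    lo, hi = int(active_range[0]), int(active_range[1])
    if lo < 1 or hi > table.n or lo > hi:
        raise ValueError("active_range must lie within (0, n_molecules]")
    rng = np.random.default_rng(seed)
    sigma = _sigma_from_precision(precision)
    counts = rng.integers(lo, hi + 1, n_frames)
    total = int(counts.sum())
    frames = np.repeat(np.arange(n_frames), counts)
    molecules = np.empty(total, dtype=int)
    pos = 0
    for c in counts:
        molecules[pos:pos + c] = rng.choice(table.n, size=c, replace=False)
        pos += c
    x = table.x[molecules]
    y = table.y[molecules]
    if precision > 0:
        x = x + rng.normal(0.0, sigma, total)
        y = y + rng.normal(0.0, sigma, total)
    return AcquisitionSeries(frame=frames, molecule=molecules, x=x, y=y,
                             n_frames=n_frames, precision=precision,
                             active_range=(lo, hi), region=region)


@dataclass
class ReconstructionResult:
    """Checkpointed reconstruction of an acquisition with autocorrelation.

    ``autocorrelation[i]`` is the Pearson correlation between the raster
    reconstructed from frames [0, checkpoint_frames[i]] and the one from
    frames [0, checkpoint_frames[i-1]] (``nan`` at i = 0).  ``stop_frame``
    is the first checkpoint whose autocorrelation exceeds the stop
    threshold — past it, additional frames mostly add repeat detections.
    """

    checkpoint_frames: np.ndarray
    autocorrelation: np.ndarray
    stop_frame: Optional[int]
    stop_index: Optional[int]
    stop_threshold: float
    pixel_size: float
    series: AcquisitionSeries
    images: Optional[list[np.ndarray]] = None

    def detections_at_checkpoint(self, index: int) -> np.ndarray:
        return self.series.detections_up_to(
            int(self.checkpoint_frames[index]))


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a.ravel().astype(float)
    b = b.ravel().astype(float)
    if a.std() == 0 or b.std() == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def reconstruct_with_autocorrelation(series: AcquisitionSeries,
                                     pixel_size: float = 20.0,
                                     interval: int = 50,
                                     stop_threshold: float = 0.990,
                                     region: Optional[RegionOfInterest] = None,
                                     keep_images: bool = False,
                                     binary: bool = True
                                     ) -> ReconstructionResult:
    """Reconstruct cumulatively and track the Pearson autocorrelation.

    The super-resolution image is rasterized every ``interval`` frames and
    compared (Pearson correlation per pixel) with the reconstruction one
    checkpoint earlier.  With ``binary=True`` (default) pixels are
    occupied/empty, so the correlation directly measures how much *new*
    image area the last frames contributed; ``binary=False`` correlates
    raw counts, which saturates much earlier because repeat detections
    land in already-bright pixels.  Autocorrelation rises quickly while
    new fluorophores are still being added and asymptotically approaches
    1 once repeat detections dominate; the first checkpoint exceeding
    ``stop_threshold`` (default 0.990) marks a reconstruction stop-point
    balancing under- against over-sampling.
    """
    if interval < 1:
        raise ValueError("interval must be >= 1")
    n_checkpoints = series.n_frames // interval
    if n_checkpoints < 2:
        raise ValueError("need at least 2 checkpoints")
    if region is None:
        region = series.region
    if region is None:
        region = RegionOfInterest.rectangle(
            series.x.min(), series.y.min(),
            series.x.max() + 1e-9, series.y.max() + 1e-9)
    xmin, ymin, xmax, ymax = region.bounds
    nx = max(1, int(np.ceil((xmax - xmin) / pixel_size)))
    ny = max(1, int(np.ceil((ymax - ymin) / pixel_size)))

    grid = np.zeros((ny, nx), dtype=np.int64)
    prev = None
    frames_cp = np.empty(n_checkpoints, dtype=int)
    autocorr = np.full(n_checkpoints, np.nan)
    images = [] if keep_images else None

    order = np.argsort(series.frame, kind="stable")
    fr = series.frame[order]
    xs = series.x[order]
    ys = series.y[order]
    # clip out-of-region detections (jitter can push past the field edge)
    inside = (xs >= xmin) & (xs < xmax) & (ys >= ymin) & (ys < ymax)
    fr, xs, ys = fr[inside], xs[inside], ys[inside]
    ix = np.floor((xs - xmin) / pixel_size).astype(int)
    iy = np.floor((ys - ymin) / pixel_size).astype(int)
    np.clip(ix, 0, nx - 1, out=ix)
    np.clip(iy, 0, ny - 1, out=iy)

    bounds = np.searchsorted(fr, (np.arange(1, n_checkpoints + 1)) * interval)
    start = 0
    stop_frame = stop_index = None
    for i, end in enumerate(bounds):
        np.add.at(grid, (iy[start:end], ix[start:end]), 1)
        start = end
        frames_cp[i] = (i + 1) * interval - 1
        img = (grid > 0).astype(np.int64) if binary else grid
        if prev is not None:
            autocorr[i] = _pearson(img, prev)
            if (stop_frame is None and np.isfinite(autocorr[i])
                    and autocorr[i] > stop_threshold):
                stop_frame = int(frames_cp[i])
                stop_index = i
        prev = img.copy()
        if keep_images:
            images.append(img.copy())
    return ReconstructionResult(
        checkpoint_frames=frames_cp, autocorrelation=autocorr,
        stop_frame=stop_frame, stop_index=stop_index,
        stop_threshold=stop_threshold, pixel_size=float(pixel_size),
        series=series, images=images)
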