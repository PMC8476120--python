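"""Stochastic simulation of myosin cluster dynamics on a thin filament.

This module generates ground-truthed traces of "active regions" -- contiguous
clusters of myosin-S1 heads bound to a regulated thin filament -- and renders
them as noisy one-dimensional fluorescence kymographs.  Each frame a cluster
of size ``n`` may:

1. collapse as a whole with probability ``pc(n)`` (concerted detachment of
   all heads in a single frame);
2. otherwise lose each head independently with probability ``pd`` (set by
   ATP binding to the bound head);
3. then gain a single head at one of its two ends (equal probability) with
   probability ``pa``.

New one-head regions nucleate on free stretches of the filament with a
per-frame probability ``p_nuc``.  The trace records every event, so any
downstream estimate (transition matrices, attachment probability, collapse
curves) can be validated against exact ground truth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import erf

from .kymo import Kymograph

__all__ = [
    "SimulationParams",
    "ImagingParams",
    "GroundTruthTrace",
    "RegionSnapshot",
    "Event",
    "simulate_cluster_dynamics",
    "render_kymograph",
    "generate_dataset",
]

PcLike = None | float | Mapping[int, float] | Callable[[int], float]


def _pc_function(pc: PcLike) -> Callable[[int], float]:
    """Normalise the collapse-probability argument to a callable of cluster size."""
    if pc is None:
        return lambda n: 0.0
    if callable(pc):
        return pc
    if isinstance(pc, Mapping):
        table = dict(pc)
        return lambda n: float(table.get(n, 0.0))
    p = float(pc)
    return lambda n: p


def _check_prob(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ValueError(f"{name} must be in [0, 1], got {value!r}")


@dataclass(frozen=True)
class SimulationParams:
    """Parameters of the discrete-time cluster-dynamics model.

    Attributes
    ----------
    pa : float
        Per-frame probability that one myosin attaches at an edge of an
        existing region.
    pd : float
        Per-frame, per-myosin independent detachment probability.  The
        default is the ATP-binding value ``1 - exp(-k_T [ATP] t)`` for
        ``k_T = 1.9 uM^-1 s^-1``, ``[ATP] = 0.1 uM`` and ``t = 0.3 s``.
    pc : None | float | mapping | callable
        Per-frame probability of concerted whole-cluster collapse as a
        function of cluster size ``n``.  ``None`` disables the channel.
    p_nuc : float
        Per-frame probability that a new one-myosin region nucleates at a
        uniform random position along the filament.
    n_max_sim : int
        Hard cap on simulated cluster size (attachment is blocked at the cap).
    filament_length_px : int
        Filament extent in pixels.
    site_spacing_nm : float
        Centre-to-centre spacing of adjacent bound myosins within a cluster.
        The default of 38.5 nm is one actin pseudo-repeat; it is sub-pixel at
        126.4 nm/pixel so rendering is insensitive to this choice.
    n_frames : int
        Number of frames to simulate.
    frame_interval_s : float
        Seconds per frame (3.3 frames/s acquisition by default).
    seed : int
        RNG seed; the same seed yields a bit-identical trace.
    min_region_separation_px : float
        Nucleation attempts closer than this to an existing region are
        discarded, reproducing the experimentally observed sparseness of
        active regions (microns of clear space between clusters).
    edge_margin_px : float
        Nucleation is restricted to at least this far from the filament
        ends, mimicking the bead-adjacent stretches of a tightrope that are
        excluded from analysis (a peak centred on the image border cannot be
        detected as a local maximum).
    pixel_nm : float
        Pixel size used to convert the filament extent to nanometres.
    initial_regions : tuple of (centre_px, n_myosins)
        Regions present at frame 0, mainly useful for controlled tests.
    """

    pa: float = 0.15
    pd: float = 0.0554
    pc: PcLike = None
    p_nuc: float = 0.15
    n_max_sim: int = 12
    filament_length_px: int = 128
    site_spacing_nm: float = 38.5
    n_frames: int = 396
    frame_interval_s: float = 0.3
    seed: int = 0
    min_region_separation_px: float = 12.0
    edge_margin_px: float = 6.0
    pixel_nm: float = 126.4
    initial_regions: tuple[tuple[float, int], ...] = ()

    def __post_init__(self) -> None:
        _check_prob("pa", self.pa)
        _check_prob("pd", self.pd)
        _check_prob("p_nuc", self.p_nuc)
        pc = _pc_function(self.pc)
        for n in range(1, self.n_max_sim + 1):
            _check_prob(f"pc({n})", pc(n))
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.site_spacing_nm <= 0:
            raise ValueError("site_spacing_nm must be > 0")
        if self.filament_length_px < 1:
            raise ValueError("filament_length_px must be >= 1")
        if self.n_max_sim < 1:
            raise ValueError("n_max_sim must be >= 1")
        if 2 * self.edge_margin_px >= self.filament_length_px:
            raise ValueError("edge_margin_px too large for the filament length")


@dataclass(frozen=True)
class ImagingParams:
    """Rendering parameters mapping bound myosins to pixel intensities."""

    pixel_nm: float = 126.4
    psf_sigma_nm: float = 150.0
    unit_intensity: float = 200.0
    unit_intensity_cv: float = 0.1
    background_offset: float = 100.0
    noise_sd: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_nm <= 0:
            raise ValueError("pixel_nm must be > 0")
        if self.psf_sigma_nm <= 0:
            raise ValueError("psf_sigma_nm must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.unit_intensity_cv < 0:
            raise ValueError("unit_intensity_cv must be >= 0")


@dataclass(frozen=True)
class Event:
    frame: int
    region_id: int
    kind: str  # nucleate | attach | detach | collapse
    n_before: int
    n_after: int
    myosin_id: int = -1
    position_nm: float = float("nan")


@dataclass(frozen=True)
class RegionSnapshot:
    region_id: int
    centre_nm: float
    myosin_ids: tuple[int, ...]
    positions_nm: tuple[float, ...]

    @property
    def occupancy(self) -> int:
        return len(self.myosin_ids)


@dataclass
class GroundTruthTrace:
    """Per-frame region snapshots plus a complete event log."""

    params: SimulationParams
    frames: list[list[RegionSnapshot]]
    events: list[Event]

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def occupancy_series(self) -> dict[int, tuple[int, list[int]]]:
        """Per-region occupancy time series.

        Returns a mapping ``region_id -> (first_frame, counts)`` where
        ``counts[k]`` is the occupancy at frame ``first_frame + k``.  A region
        that dies before the movie ends carries a terminal 0; a region still
        alive at the last frame is right-censored (no terminal 0), matching
        how tracked experimental regions are treated.
        """
        first: dict[int, int] = {}
        series: dict[int, list[int]] = {}
        alive_prev: set[int] = set()
        for f, regions in enumerate(self.frames):
            seen = set()
            for snap in regions:
                rid = snap.region_id
                seen.add(rid)
                if rid not in series:
                    first[rid] = f
                    series[rid] = []
                series[rid].append(snap.occupancy)
            for rid in alive_prev - seen:
                series[rid].append(0)  # death frame
            alive_prev = seen
        return {rid: (first[rid], series[rid]) for rid in series}

    def count_series(self) -> list[np.ndarray]:
        """Occupancy series per region as float arrays (terminal 0 included),
        the ground-truth twin of tracked-and-calibrated count series."""
        return [np.asarray(counts, dtype=np.float64)
                for _, counts in self.occupancy_series().values()]

    def events_to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [dataclasses.asdict(e) for e in self.events],
            columns=["frame", "region_id", "kind", "n_before", "n_after",
                     "myosin_id", "position_nm"],
        )

    def occupancy_to_dataframe(self) -> pd.DataFrame:
        rows = []
        for rid, (f0, counts) in self.occupancy_series().items():
            for k, n in enumerate(counts):
                rows.append((rid, f0 + k, n))
        return pd.DataFrame(rows, columns=["region_id", "frame", "occupancy"])

    def to_event_csv(self, path) -> None:
        self.events_to_dataframe().to_csv(path, index=False)

    def to_occupancy_csv(self, path) -> None:
        self.occupancy_to_dataframe().to_csv(path, index=False)


class _Region:
    __slots__ = ("rid", "sites", "mids", "origin_nm", "spacing_nm")

    def __init__(self, rid: int, origin_nm: float, spacing_nm: float) -> None:
        self.rid = rid
        self.sites: list[int] = []
        self.mids: list[int] = []
        self.origin_nm = origin_nm
        self.spacing_nm = spacing_nm

    def positions_nm(self) -> tuple[float, ...]:
        return tuple(self.origin_nm + s * self.spacing_nm for s in self.sites)

    def centre_nm(self) -> float:
        pos = self.positions_nm()
        return float(np.mean(pos)) if pos else float("nan")

    def snapshot(self) -> RegionSnapshot:
        return RegionSnapshot(self.rid, self.centre_nm(),
                              tuple(self.mids), self.positions_nm())


def simulate_cluster_dynamics(params: SimulationParams) -> GroundTruthTrace:
    """Run the discrete-time Markov simulation of cluster dynamics.

    Within each frame the event order is fixed: concerted collapse first
    (mutually exclusive with stochastic detachment in that frame), then
    independent per-myosin detachment, then single-myosin edge attachment,
    then nucleation of new regions.  Frame 0 holds the initial state;
    events are stamped with the frame at which their outcome is first
    visible.
    """
    rng = np.random.default_rng(params.seed)
    pc = _pc_function(params.pc)
    spacing = params.site_spacing_nm
    fil_nm = params.filament_length_px * params.pixel_nm
    sep_nm = params.min_region_separation_px * params.pixel_nm

    regions: list[_Region] = []
    events: list[Event] = []
    frames: list[list[RegionSnapshot]] = []
    next_rid = 0
    next_mid = 0

    for centre_px, n in params.initial_regions:
        reg = _Region(next_rid, centre_px * params.pixel_nm, spacing)
        next_rid += 1
        for k in range(int(n)):
            reg.sites.append(k - int(n) // 2)
            reg.mids.append(next_mid)
            next_mid += 1
        regions.append(reg)

    def region_centres() -> list[float]:
        return [r.centre_nm() for r in regions]

    frames.append([r.snapshot() for r in regions])

    for f in range(1, params.n_frames):
        survivors: list[_Region] = []
        for reg in regions:
            n = len(reg.sites)
            p_collapse = pc(n)
            if p_collapse > 0.0 and rng.random() < p_collapse:
                events.append(Event(f, reg.rid, "collapse", n, 0))
                continue  # all heads gone, region closed
            if params.pd > 0.0 and n > 0:
                u = rng.random(n)
                keep = u >= params.pd
                if not keep.all():
                    for idx in np.flatnonzero(~keep):
                        events.append(Event(
                            f, reg.rid, "detach", n, n - 1,
                            myosin_id=reg.mids[idx],
                            position_nm=reg.origin_nm + reg.sites[idx] * spacing,
                        ))
                        n -= 1
                    reg.sites = [s for s, k in zip(reg.sites, keep) if k]
                    reg.mids = [m for m, k in zip(reg.mids, keep) if k]
            if not reg.sites:
                continue  # emptied by detachment: closed, no attachment
            if (params.pa > 0.0 and len(reg.sites) < params.n_max_sim
                    and rng.random() < params.pa):
                if rng.random() < 0.5:
                    site = reg.sites[0] - 1
                    reg.sites.insert(0, site)
                    reg.mids.insert(0, next_mid)
                else:
                    site = reg.sites[-1] + 1
                    reg.sites.append(site)
                    reg.mids.append(next_mid)
                events.append(Event(
                    f, reg.rid, "attach", len(reg.sites) - 1, len(reg.sites),
                    myosin_id=next_mid,
                    position_nm=reg.origin_nm + site * spacing,
                ))
                next_mid += 1
            survivors.append(reg)
        regions = survivors

        if params.p_nuc > 0.0 and rng.random() < params.p_nuc:
            margin_nm = params.edge_margin_px * params.pixel_nm
            pos = rng.uniform(margin_nm, fil_nm - margin_nm)
            centres = region_centres()
            if all(abs(pos - c) >= sep_nm for c in centres):
                reg = _Region(next_rid, pos, spacing)
                reg.sites.append(0)
                reg.mids.append(next_mid)
                events.append(Event(f, reg.rid, "nucleate", 0, 1,
                                    myosin_id=next_mid, position_nm=pos))
                next_rid += 1
                next_mid += 1
                regions.append(reg)

        frames.append([r.snapshot() for r in regions])

    return GroundTruthTrace(params=params, frames=frames, events=events)


def render_kymograph(trace: GroundTruthTrace, imaging: ImagingParams,
                     source_id: str = "synthetic") -> Kymograph:
    """Render a ground-truth trace as a noisy fluorescence kymograph.

    Each bound myosin contributes a pixel-integrated 1-D Gaussian profile
    whose integrated intensity is drawn once, at first appearance, from
    ``Normal(unit_intensity, cv * unit_intensity)`` (clipped at zero) --
    modelling a fixed fluorophore brightness.  A constant background offset
    and i.i.d. Gaussian read noise are added and the result is clipped at 0.
    """
    rng = np.random.default_rng(imaging.seed)
    p = trace.params
    n_px = p.filament_length_px
    n_frames = trace.n_frames
    sigma_px = imaging.psf_sigma_nm / imaging.pixel_nm
    half_width = max(3, int(np.ceil(5 * sigma_px)))

    brightness: dict[int, float] = {}

    def bright(mid: int) -> float:
        b = brightness.get(mid)
        if b is None:
            b = imaging.unit_intensity
            if imaging.unit_intensity_cv > 0:
                b = rng.normal(b, imaging.unit_intensity_cv * imaging.unit_intensity)
            b = max(b, 0.0)
            brightness[mid] = b
        return b

    img = np.zeros((n_frames, n_px), dtype=np.float64)
    edges = np.arange(n_px + 1, dtype=np.float64)  # pixel boundaries, px units
    sq2 = np.sqrt(2.0)
    for f, regions in enumerate(trace.frames):
        row = img[f]
        for snap in regions:
            for mid, pos_nm in zip(snap.myosin_ids, snap.positions_nm):
                pos_px = pos_nm / imaging.pixel_nm
                lo = max(0, int(pos_px) - half_width)
                hi = min(n_px, int(pos_px) + half_width + 1)
                if hi <= lo:
                    continue
                z = (edges[lo:hi + 1] - pos_px) / (sigma_px * sq2)
                cdf = 0.5 * (1.0 + erf(z))
                row[lo:hi] += bright(mid) * np.diff(cdf)

    img += imaging.background_offset
    if imaging.noise_sd > 0:
        img += rng.normal(0.0, imaging.noise_sd, size=img.shape)
    np.clip(img, 0.0, None, out=img)
    return Kymograph(intensity=img, frame_interval_s=p.frame_interval_s,
                     pixel_nm=imaging.pixel_nm, source_id=source_id)


def generate_dataset(
    params: SimulationParams,
    imaging: ImagingParams,
    n_kymographs: int,
    seed: int = 0,
) -> list[tuple[Kymograph, GroundTruthTrace]]:
    """Generate independent replicate kymographs with derived per-replicate seeds.

    Reproducible: the master ``seed`` fully determines every replicate.
    """
    if n_kymographs < 1:
        raise ValueError("n_kymographs must be >= 1")
    ss = np.random.SeedSequence(seed)
    state = ss.generate_state(2 * n_kymographs)
    out = []
    for i in range(n_kymographs):
        sim_seed = int(state[2 * i]) & 0x7FFFFFFF
        img_seed = int(state[2 * i + 1]) & 0x7FFFFFFF
        p_i = dataclasses.replace(params, seed=sim_seed)
        im_i = dataclasses.replace(imaging, seed=img_seed)
        trace = simulate_cluster_dynamics(p_i)
        kymo = render_kymograph(trace, im_i, source_id=f"synthetic-{i:03d}")
        out.append((kymo, trace))
    return out
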