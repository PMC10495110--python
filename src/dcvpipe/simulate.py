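"""Synthetic fluorescence movies with known ground truth.

Three generators emulate the imaging experiments the pipeline analyzes:

* :func:`generate_fusion_movie` — sparse pHluorin-labelled puncta on a dim
  neurite background; stimulus-locked fusion events with sub-second rise and
  exponential decay; an optional terminal NH4Cl segment in which every
  punctum brightens by a dequench factor.
* :func:`generate_rush_movie` — a Golgi region that fills linearly with a
  synchronously released cargo and then drains with first-order kinetics,
  with optional lateral stage drift.
* :func:`generate_kymo_movie` — particles moving at constant signed velocity
  along a straight neurite path, for kymograph tracking.

The noise model is the standard shot + read camera model: Poisson noise on
the signal (scaled by ``noise_poisson_scale``) followed by additive Gaussian
read noise.  Identical configurations with identical seeds produce
bit-identical stacks.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .core import Movie, StimProtocol

__all__ = [
    "EventSpec",
    "SimConfig",
    "GroundTruth",
    "generate_fusion_movie",
    "generate_rush_movie",
    "generate_kymo_movie",
    "write_movie",
    "read_ground_truth",
]


@dataclass(frozen=True)
class EventSpec:
    """A single fusion event to realize in a simulated movie.

    ``peak_ratio`` multiplies the punctum's baseline brightness at the peak;
    the rise is linear over ``rise_time`` seconds and the return to baseline
    is exponential with time constant ``decay_tau``.
    """

    punctum_id: int
    onset_time: float
    peak_ratio: float
    rise_time: float = 0.25
    decay_tau: float = 5.0


@dataclass
class SimConfig:
    """Acquisition and scene parameters for a simulated pHluorin recording.

    Defaults reproduce a typical single-neuron secretion protocol:
    acquisition at 2 Hz for 2 min (240 frames), 30 s of baseline, then
    16 trains of 50 pulses at 50 Hz separated by 0.5 s.
    """

    image_shape: tuple[int, int] = (64, 64)
    frame_interval: float = 0.5
    n_frames: int = 240
    pixel_size: float = 0.2
    baseline_duration: float = 30.0
    stim_protocol: StimProtocol = field(default_factory=StimProtocol)
    n_puncta: int = 20
    punctum_sigma: float = 1.2
    punctum_amplitude: float = 60.0
    background_level: float = 20.0
    events: tuple[EventSpec, ...] = ()
    nh4cl_window: tuple[float, float] | None = None
    dequench_factor: float = 5.0
    punctum_min_separation: float = 0.0
    noise_gaussian_sd: float = 0.0
    noise_poisson_scale: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.image_shape = tuple(self.image_shape)
        if self.nh4cl_window is not None:
            self.nh4cl_window = tuple(self.nh4cl_window)
        self.events = tuple(self.events)
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.n_frames < 1:
            raise ValueError("n_frames must be positive")
        if self.dequench_factor < 1:
            raise ValueError("dequench_factor must be >= 1")
        duration = self.n_frames * self.frame_interval
        for ev in self.events:
            if not 0 <= ev.onset_time < duration:
                raise ValueError(
                    f"event onset {ev.onset_time}s outside recording (0-{duration}s)"
                )
            if ev.rise_time >= duration:
                raise ValueError("event rise_time exceeds recording duration")
            if ev.peak_ratio < 1:
                raise ValueError("peak_ratio must be >= 1")

    @property
    def duration(self) -> float:
        return self.n_frames * self.frame_interval


@dataclass
class GroundTruth:
    """What the simulator actually put in a movie.

    Only the fields relevant to the generated experiment are populated.
    """

    puncta_positions: list[tuple[float, float]] = field(default_factory=list)
    events: list[EventSpec] = field(default_factory=list)
    track_table: pd.DataFrame | None = None
    rush_params: dict | None = None
    golgi_mask: np.ndarray | None = None


def _gaussian_spot(shape: tuple[int, int], center: tuple[float, float], sigma: float) -> np.ndarray:
    rows = np.arange(shape[0])[:, None]
    cols = np.arange(shape[1])[None, :]
    r0, c0 = center
    return np.exp(-((rows - r0) ** 2 + (cols - c0) ** 2) / (2.0 * sigma**2))


def _place_puncta(config: SimConfig, rng: np.random.Generator) -> list[tuple[float, float]]:
    """Uniform random puncta positions, optionally with a minimum separation."""
    margin = max(3.0, 3.0 * config.punctum_sigma)
    lo_r, hi_r = margin, config.image_shape[0] - margin
    lo_c, hi_c = margin, config.image_shape[1] - margin
    positions: list[tuple[float, float]] = []
    attempts = 0
    while len(positions) < config.n_puncta:
        r = rng.uniform(lo_r, hi_r)
        c = rng.uniform(lo_c, hi_c)
        if config.punctum_min_separation > 0:
            ok = all(
                np.hypot(r - pr, c - pc) >= config.punctum_min_separation
                for pr, pc in positions
            )
            if not ok:
                attempts += 1
                if attempts > 20000:
                    raise RuntimeError(
                        "could not place puncta at requested minimum separation"
                    )
                continue
        positions.append((r, c))
    return positions


def _apply_noise(
    stack: np.ndarray,
    poisson_scale: float,
    gaussian_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    out = stack
    if poisson_scale > 0:
        out = rng.poisson(np.maximum(out, 0) / poisson_scale) * poisson_scale
        out = out.astype(float)
    if gaussian_sd > 0:
        out = out + rng.normal(0.0, gaussian_sd, size=out.shape)
    return out


def _quantize_event(ev: EventSpec, frame_interval: float) -> EventSpec:
    """Snap an event's onset and rise to the frame grid.

    The rise is linear in time and quantized to the frame grid: the onset
    lands on a frame time and the rise spans a whole number of frames (a
    sub-frame rise spans exactly one), so frame-level rise-time criteria can
    be tested without aliasing from off-grid sampling.
    """
    onset = round(ev.onset_time / frame_interval) * frame_interval
    rise = max(1, int(np.ceil(ev.rise_time / frame_interval - 1e-9))) * frame_interval
    return EventSpec(
        punctum_id=ev.punctum_id,
        onset_time=onset,
        peak_ratio=ev.peak_ratio,
        rise_time=rise,
        decay_tau=ev.decay_tau,
    )


def _event_modulation(ev: EventSpec, times: np.ndarray) -> np.ndarray:
    """Multiplicative brightness modulation of one punctum over time.

    Linear ramp from 1 to ``peak_ratio`` over ``rise_time``, then
    exponential relaxation back to 1 with ``decay_tau``.
    """
    m = np.ones_like(times)
    t_peak = ev.onset_time + ev.rise_time
    rising = (times > ev.onset_time) & (times < t_peak - 1e-9)
    if ev.rise_time > 0:
        m[rising] = 1.0 + (ev.peak_ratio - 1.0) * (times[rising] - ev.onset_time) / ev.rise_time
    decaying = times >= t_peak - 1e-9
    m[decaying] = 1.0 + (ev.peak_ratio - 1.0) * np.exp(
        -np.maximum(times[decaying] - t_peak, 0.0) / ev.decay_tau
    )
    return m


def generate_fusion_movie(config: SimConfig) -> tuple[Movie, GroundTruth]:
    """Simulate a pHluorin secretion recording with known events.

    Each punctum is a Gaussian spot of width ``punctum_sigma`` and baseline
    peak brightness ``punctum_amplitude`` on a flat background.  Each event
    multiplies its punctum's brightness by ``peak_ratio`` with a linear ramp
    of duration ``rise_time`` followed by exponential decay; frames inside
    ``nh4cl_window`` multiply *all* puncta by ``dequench_factor``
    simultaneously (the ammonium pulse neutralizes every vesicle lumen at
    once).  Noise is added last.

    Returns the movie and the realized ground truth.
    """
    rng = np.random.default_rng(config.rng_seed)
    positions = _place_puncta(config, rng)
    for ev in config.events:
        if not 0 <= ev.punctum_id < len(positions):
            raise ValueError(f"event references unknown punctum {ev.punctum_id}")
        if config.nh4cl_window is not None:
            t_peak = ev.onset_time + ev.rise_time
            if t_peak + 3 * ev.decay_tau > config.nh4cl_window[0]:
                warnings.warn(
                    f"event at {ev.onset_time}s decays into the NH4Cl window",
                    stacklevel=2,
                )

    times = np.arange(config.n_frames) * config.frame_interval
    shape = config.image_shape

    # per-punctum brightness over time; realized events are frame-quantized
    realized = [_quantize_event(ev, config.frame_interval) for ev in config.events]
    modulation = np.ones((len(positions), config.n_frames))
    for ev in realized:
        modulation[ev.punctum_id] *= _event_modulation(ev, times)
    if config.nh4cl_window is not None:
        start, end = config.nh4cl_window
        in_window = (times >= start) & (times < end)
        modulation[:, in_window] *= config.dequench_factor

    spots = np.stack(
        [_gaussian_spot(shape, pos, config.punctum_sigma) for pos in positions]
    ) if positions else np.zeros((0,) + shape)

    stack = np.full((config.n_frames,) + shape, float(config.background_level))
    if len(positions):
        # (T, H, W) += sum_j m_j(t) * A * spot_j
        stack += np.einsum("jt,jhw->thw", modulation, spots) * config.punctum_amplitude

    stack = _apply_noise(stack, config.noise_poisson_scale, config.noise_gaussian_sd, rng)

    movie = Movie(
        data=stack,
        frame_interval=config.frame_interval,
        pixel_size=config.pixel_size,
        nh4cl_window=config.nh4cl_window,
    )
    truth = GroundTruth(puncta_positions=positions, events=realized)
    return movie, truth


def generate_rush_movie(
    k_true: float,
    t_peak_true: float,
    plateau: float = 0.0,
    n_frames: int = 25,
    frame_interval: float = 5.0,
    drift: tuple[float, float] = (0.0, 0.0),
    noise_sd: float = 0.0,
    rng_seed: int = 0,
    *,
    image_shape: tuple[int, int] = (64, 64),
    biotin_frame: int = 3,
    peak_value: float = 4.0,
    golgi_radius: float = 7.0,
    amplitude: float = 100.0,
    background_level: float = 5.0,
) -> tuple[Movie, GroundTruth]:
    """Simulate a RUSH pulse-chase recording of Golgi cargo flux.

    The Golgi-region mean intensity, normalized to the pre-biotin baseline,
    is 1 before biotin addition, rises linearly to ``peak_value`` at
    ``t_peak_true`` minutes after biotin, then follows
    ``plateau + (peak - plateau) * exp(-k_true * (t - t_peak))`` where
    ``plateau`` is given peak-normalized in ``[0, 1)``.  The whole frame is
    translated by the cumulative ``drift`` (pixels/frame).  Times are in
    minutes; ``k_true`` is per minute.
    """
    if k_true <= 0:
        raise ValueError("k_true must be positive")
    if not 0 <= plateau < 1:
        raise ValueError("plateau must be in [0, 1) peak-normalized")
    if n_frames < 1:
        raise ValueError("n_frames must be positive")
    if biotin_frame < 1:
        raise ValueError("biotin_frame must be >= 1 so a baseline exists")

    rng = np.random.default_rng(rng_seed)
    times = np.arange(n_frames) * frame_interval  # minutes from recording start
    t_biotin = biotin_frame * frame_interval
    t = times - t_biotin  # minutes from biotin addition

    # normalized trace (baseline == 1)
    trace = np.ones(n_frames)
    rising = (t > 0) & (t < t_peak_true)
    trace[rising] = 1.0 + (peak_value - 1.0) * t[rising] / t_peak_true
    plateau_abs = plateau * peak_value
    post = t >= t_peak_true
    trace[post] = plateau_abs + (peak_value - plateau_abs) * np.exp(
        -k_true * (t[post] - t_peak_true)
    )

    center = (image_shape[0] / 2.0, image_shape[1] / 2.0)
    rows = np.arange(image_shape[0])[:, None]
    cols = np.arange(image_shape[1])[None, :]
    golgi = (rows - center[0]) ** 2 + (cols - center[1]) ** 2 <= golgi_radius**2

    base = np.full(image_shape, float(background_level))
    stack = np.empty((n_frames,) + image_shape)
    for i in range(n_frames):
        frame = base.copy()
        frame[golgi] += amplitude * trace[i]
        if drift != (0.0, 0.0):
            dy = int(round(drift[0] * i))
            dx = int(round(drift[1] * i))
            frame = np.roll(np.roll(frame, dy, axis=0), dx, axis=1)
        stack[i] = frame
    if noise_sd > 0:
        stack = stack + rng.normal(0.0, noise_sd * amplitude, size=stack.shape)

    movie = Movie(data=stack, frame_interval=frame_interval * 60.0, pixel_size=0.3)
    truth = GroundTruth(
        rush_params={
            "k_true": k_true,
            "t_peak_true": t_peak_true,
            "plateau_true": plateau,
            "peak_value": peak_value,
            "biotin_frame": biotin_frame,
            "frame_interval_min": frame_interval,
        },
        golgi_mask=golgi,
    )
    return movie, truth


def generate_kymo_movie(
    n_particles: int,
    velocities: list[float] | np.ndarray | None = None,
    pixel_size: float = 0.2,
    frame_interval: float = 2.0,
    n_frames: int = 90,
    path_length: float = 40.0,
    noise_sd: float = 0.0,
    rng_seed: int = 0,
    *,
    spot_sigma: float = 1.0,
    amplitude: float = 80.0,
    background_level: float = 10.0,
    image_height: int = 21,
) -> tuple[Movie, GroundTruth]:
    """Simulate particles moving at constant velocity along a straight path.

    The path runs horizontally through the image centre row, soma at column
    0.  Velocities are signed µm/s (positive = anterograde, away from the
    soma); each particle is a Gaussian spot that is truncated when it leaves
    the path.  If ``velocities`` is None, speeds are drawn uniformly from
    0.5-1.5 µm/s with random sign.
    """
    rng = np.random.default_rng(rng_seed)
    if velocities is None:
        speeds = rng.uniform(0.5, 1.5, size=n_particles)
        signs = rng.choice([-1.0, 1.0], size=n_particles)
        velocities = speeds * signs
    velocities = np.asarray(velocities, dtype=float)
    if len(velocities) != n_particles:
        raise ValueError("velocities length must equal n_particles")
    for v in velocities:
        if abs(v) * frame_interval >= path_length:
            raise ValueError("particle crosses the whole path in one frame")

    n_cols = int(round(path_length / pixel_size))
    shape = (image_height, n_cols)
    row0 = image_height // 2
    times = np.arange(n_frames) * frame_interval

    # start positions: leave room so most particles stay in view
    starts = rng.uniform(0.15 * path_length, 0.85 * path_length, size=n_particles)

    stack = np.full((n_frames,) + shape, float(background_level))
    records = []
    for pid, (v, x0) in enumerate(zip(velocities, starts)):
        pos_um = x0 + v * times
        visible = (pos_um >= 0) & (pos_um < path_length)
        if not visible.any():
            continue
        first, last = np.nonzero(visible)[0][[0, -1]]
        for i in np.nonzero(visible)[0]:
            col = pos_um[i] / pixel_size
            stack[i] += amplitude * _gaussian_spot(shape, (row0, col), spot_sigma)
        records.append(
            {
                "particle_id": pid,
                "velocity_um_s": v,
                "start_um": x0,
                "t_start_s": times[first],
                "t_end_s": times[last],
            }
        )
    if noise_sd > 0:
        stack = stack + rng.normal(0.0, noise_sd * amplitude, size=stack.shape)

    movie = Movie(data=stack, frame_interval=frame_interval, pixel_size=pixel_size)
    truth = GroundTruth(track_table=pd.DataFrame(records))
    return movie, truth


# --------------------------------------------------------------------------
# on-disk format: multi-page 16-bit TIFF + JSON sidecar + ground-truth CSV


def write_movie(movie: Movie, path: str | Path, truth: GroundTruth | None = None) -> Path:
    """Write a movie as multi-page 16-bit TIFF with a JSON metadata sidecar.

    The sidecar (``<stem>.json``) carries the frame interval, pixel size and
    NH4Cl window unambiguously; if ground truth is given it is written next
    to the stack as CSV tables.
    """
    path = Path(path)
    data = np.clip(np.round(movie.data), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, data, photometric="minisblack")
    sidecar = {
        "frame_interval_s": movie.frame_interval,
        "pixel_size_um": movie.pixel_size,
        "nh4cl_window_s": list(movie.nh4cl_window) if movie.nh4cl_window else None,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    if truth is not None:
        stem = path.with_suffix("")
        if truth.puncta_positions:
            pd.DataFrame(
                truth.puncta_positions, columns=["row", "col"]
            ).rename_axis("punctum_id").to_csv(f"{stem}_puncta.csv")
        if truth.events:
            pd.DataFrame([vars(e) for e in truth.events]).to_csv(
                f"{stem}_events.csv", index=False
            )
        if truth.track_table is not None and len(truth.track_table):
            truth.track_table.to_csv(f"{stem}_tracks.csv", index=False)
        if truth.rush_params is not None:
            Path(f"{stem}_rush.json").write_text(json.dumps(truth.rush_params, indent=2))
    return path


def read_ground_truth(stem: str | Path) -> GroundTruth:
    """Read ground-truth tables written next to a simulated stack."""
    stem = Path(stem)
    truth = GroundTruth()
    p = Path(f"{stem}_puncta.csv")
    if p.exists():
        df = pd.read_csv(p)
        truth.puncta_positions = list(zip(df["row"], df["col"]))
    p = Path(f"{stem}_events.csv")
    if p.exists():
        truth.events = [EventSpec(**row) for row in pd.read_csv(p).to_dict("records")]
    p = Path(f"{stem}_tracks.csv")
    if p.exists():
        truth.track_table = pd.read_csv(p)
    p = Path(f"{stem}_rush.json")
    if p.exists():
        truth.rush_params = json.loads(p.read_text())
    return truth
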