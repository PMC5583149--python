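"""Synthetic population-coded tactile input stream.

Emulates the input a tactile-exploration setup feeds to the field: per
frame there are 0-2 simultaneous contacts (two-finger contacts occur at
opposing orientations, 180 degrees apart), each with a circularity value
in (0, 1) rating how circular the contact patch is (1 = flat surface,
0 = sharp edge).  A population code over the periodic orientation
dimension encodes circularity as activation amplitude, Gaussian-blurred
across neighboring orientations.  Frames arrive at ~3.33 fps and a base
block can be looped to arbitrary duration, mimicking a looped recording.

Distribution choices the recordings leave open (circularity law, contact
counts, blur width, temporal persistence) are explicit scenario
parameters; defaults are documented stand-ins, not estimates of any
particular dataset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .field import FieldGrid

__all__ = [
    "ContactEvent",
    "InputScenario",
    "InputSeries",
    "opposing_orientation",
    "sample_contacts",
    "encode_population",
    "generate_series",
    "manipulate",
]


@dataclass(frozen=True)
class ContactEvent:
    """A single tactile contact: orientation (degrees) and circularity."""

    orientation: float
    circularity: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "orientation", float(self.orientation) % 360.0)
        if not (0.0 < self.circularity < 1.0):
            raise ValueError("circularity must lie strictly in (0, 1)")


@dataclass(frozen=True)
class InputScenario:
    """Parameters of the synthetic stream.

    fps:
        Frame rate (default 3.33 frames per second).
    duration:
        Total stream length in seconds.
    p_contacts:
        Probabilities of 0, 1 or 2 simultaneous contacts per (re)draw.
    circularity_alpha, circularity_beta:
        Beta-law parameters of the circularity draw; the right-skewed
        default (2, 5) makes high-circularity contacts a minority.
    blur_sigma:
        Gaussian blur across orientation, in degrees (default 10.8, i.e.
        3 sites on a 100-site/360-degree grid).
    amplitude_scale:
        Activation units per unit circularity (default 6, giving raw
        amplitudes in [0, 6]).
    combine:
        How overlapping bumps merge: "max" (default; respects the
        encoding's amplitude ceiling) or "sum".
    persistence_mean:
        Mean number of consecutive frames a contact configuration
        persists (geometric law, default 2) - gives the stream its
        slowly varying structure.
    loop_seconds:
        Length of the base block that is generated once and looped
        (default 315 s, one input period); None disables looping.
    scale_factor, offset, switch_time:
        Manipulation applied to frames at t >= switch_time:
        ``S -> scale_factor * S + offset`` (used by the distribution-shift
        experiments: x1/6, x6, -12).
    seed:
        Seed of the generator's random stream.
    """

    duration: float
    fps: float = 3.33
    p_contacts: tuple[float, float, float] = (0.3, 0.4, 0.3)
    circularity_alpha: float = 2.0
    circularity_beta: float = 5.0
    blur_sigma: float = 10.8
    amplitude_scale: float = 6.0
    combine: str = "max"
    persistence_mean: float = 2.0
    loop_seconds: float | None = 315.0
    scale_factor: float = 1.0
    offset: float = 0.0
    switch_time: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fps <= 0 or self.duration <= 0:
            raise ValueError("fps and duration must be positive")
        p = np.asarray(self.p_contacts, dtype=float)
        if p.shape != (3,) or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("p_contacts must be 3 non-negative probabilities summing to 1")
        if self.amplitude_scale <= 0:
            raise ValueError("amplitude_scale must be positive")
        if self.combine not in ("max", "sum"):
            raise ValueError("combine must be 'max' or 'sum'")
        if self.persistence_mean < 1:
            raise ValueError("persistence_mean must be >= 1 frame")

    @property
    def frame_dt(self) -> float:
        return 1.0 / self.fps


@dataclass
class InputSeries:
    """Frame-sampled input ``S(x, t)``, one row per frame.

    Frames are presented with zero-order hold: the simulator repeats each
    frame for every Euler step until the next one.
    """

    frames: np.ndarray  # (n_frames, n_sites)
    frame_dt: float

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def duration(self) -> float:
        return self.n_frames * self.frame_dt

    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_dt

    def to_csv(self, path_or_buf) -> None:
        """Write the series as CSV: metadata comment lines, a header row,
        then one row per frame (time followed by per-site values)."""
        if isinstance(path_or_buf, (str, bytes)):
            with open(path_or_buf, "w") as fh:
                self.to_csv(fh)
            return
        fh = path_or_buf
        n_sites = self.frames.shape[1]
        fh.write(f"# frame_dt={self.frame_dt!r}\n")
        fh.write(f"# n_sites={n_sites}\n")
        fh.write("time," + ",".join(f"site_{i}" for i in range(n_sites)) + "\n")
        for k in range(self.n_frames):
            row = ",".join(repr(float(v)) for v in self.frames[k])
            fh.write(f"{float(k * self.frame_dt)!r},{row}\n")

    @classmethod
    def from_csv(cls, path_or_buf) -> "InputSeries":
        if isinstance(path_or_buf, (str, bytes)):
            with open(path_or_buf) as fh:
                return cls.from_csv(fh)
        fh = path_or_buf
        meta: dict[str, str] = {}
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, val = line[1:].strip().partition("=")
            meta[key.strip()] = val.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        data = np.loadtxt(fh, delimiter=",", skiprows=1, ndmin=2)
        frame_dt = float(meta.get("frame_dt", data[1, 0] - data[0, 0] if len(data) > 1 else 1.0))
        return cls(frames=data[:, 1:], frame_dt=frame_dt)


def opposing_orientation(orientation: float) -> float:
    """Orientation of the second finger: the first plus 180 degrees, wrapped."""
    return (orientation + 180.0) % 360.0


def sample_contacts(scenario: InputScenario, rng: np.random.Generator) -> list[ContactEvent]:
    """Draw one contact configuration (0-2 contacts).

    The contact count follows ``p_contacts``; the first orientation is
    uniform on [0, 360); a second contact sits at the opposing
    orientation.  Circularities are independent Beta draws.
    """
    count = int(rng.choice(3, p=scenario.p_contacts))
    if count == 0:
        return []
    theta = float(rng.uniform(0.0, 360.0))
    orientations = [theta] if count == 1 else [theta, opposing_orientation(theta)]
    contacts = []
    for o in orientations:
        c = float(rng.beta(scenario.circularity_alpha, scenario.circularity_beta))
        # Beta draws can hit the closed endpoints at floating-point
        # resolution; nudge into the open interval.
        c = min(max(c, 1e-12), 1.0 - 1e-12)
        contacts.append(ContactEvent(o, c))
    return contacts


def encode_population(
    contacts: list[ContactEvent], grid: FieldGrid, scenario: InputScenario
) -> np.ndarray:
    """Population-encode a contact configuration into one input frame.

    Each contact contributes a circular Gaussian bump centered at its
    orientation, peak amplitude ``amplitude_scale * circularity``, width
    ``blur_sigma`` degrees.  Overlapping bumps combine by element-wise
    maximum (default) or sum.
    """
    frame = np.zeros(grid.n_sites)
    if not contacts:
        return frame
    sites = grid.sites
    half = grid.domain_extent / 2.0
    for contact in contacts:
        delta = np.abs(sites - contact.orientation)
        delta = np.minimum(delta, grid.domain_extent - delta)  # circular distance, degrees
        bump = (
            scenario.amplitude_scale
            * contact.circularity
            * np.exp(-(delta**2) / (2.0 * scenario.blur_sigma**2))
        )
        if scenario.combine == "max":
            np.maximum(frame, bump, out=frame)
        else:
            frame += bump
    return frame


def generate_series(scenario: InputScenario, grid: FieldGrid) -> InputSeries:
    """Generate the full frame sequence for a scenario.

    A base block of ``loop_seconds`` is generated once from the scenario
    seed and tiled to the requested duration (emulating a looped
    recording); contact configurations persist for a geometric number of
    frames.  Any configured manipulation is applied afterwards.
    """
    n_frames = math.ceil(scenario.duration * scenario.fps)
    if scenario.loop_seconds is not None:
        block_frames = min(n_frames, math.ceil(scenario.loop_seconds * scenario.fps))
    else:
        block_frames = n_frames
    rng = np.random.default_rng(scenario.seed)
    block = np.empty((block_frames, grid.n_sites))
    remaining = 0
    contacts: list[ContactEvent] = []
    p_redraw = 1.0 / scenario.persistence_mean
    for k in range(block_frames):
        if remaining <= 0:
            contacts = sample_contacts(scenario, rng)
            remaining = int(rng.geometric(p_redraw))
        block[k] = encode_population(contacts, grid, scenario)
        remaining -= 1
    reps = math.ceil(n_frames / block_frames)
    frames = np.tile(block, (reps, 1))[:n_frames]
    series = InputSeries(frames=frames, frame_dt=scenario.frame_dt)
    if scenario.switch_time is not None:
        series = manipulate(series, scenario)
    return series


def manipulate(series: InputSeries, scenario: InputScenario) -> InputSeries:
    """Apply the distribution shift ``S -> scale_factor * S + offset`` to
    every frame at ``t >= switch_time``; earlier frames are untouched."""
    if scenario.switch_time is None:
        return series
    if not (0 <= scenario.switch_time <= series.duration):
        raise ValueError("switch_time must lie within the series duration")
    frames = series.frames.copy()
    times = series.frame_times()
    late = times >= scenario.switch_time
    frames[late] = scenario.scale_factor * frames[late] + scenario.offset
    return InputSeries(frames=frames, frame_dt=series.frame_dt)
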