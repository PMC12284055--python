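"""Adjacent drive/measure protocol, frames, and the frame text format.

A frame is one complete cycle of the adjacent protocol on an electrode
ring: current is driven through each consecutive electrode pair in turn and
the RMS differential voltage is read across every consecutive pair not
touching the drive, giving ``n*(n-3)`` values — an 8x5 matrix for the
8-electrode device.  Frames are stored one per text file (``Frame<k>.txt``,
whitespace-delimited volts) with ``Frame0.txt`` as the homogeneous
reference.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "ElectrodeLayout",
    "InjectionPattern",
    "Frame",
    "NoiseModel",
    "FrameFormatError",
    "adjacent_pattern",
    "differential_voltage",
    "acquire_frames",
    "write_frames",
    "read_frames",
]


class FrameFormatError(ValueError):
    """A frame file does not parse as the expected matrix."""


@dataclass(frozen=True)
class ElectrodeLayout:
    """Electrode ring geometry and the electrode-to-pin wiring.

    ``angles`` are the boundary positions in radians (strictly increasing in
    [0, 2π), counterclockwise, electrode 1 at angle 0 by default).
    ``pin_permutation`` maps the geometric electrode index to the device
    connector pin, so a non-sequential harness can be expressed without
    touching the protocol itself.
    """

    n_electrodes: int
    angles: tuple[float, ...]
    pin_permutation: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.angles) != self.n_electrodes:
            raise ValueError("need one angle per electrode")
        a = np.asarray(self.angles)
        if np.any(a < 0) or np.any(a >= 2 * np.pi) or np.any(np.diff(a) <= 0):
            raise ValueError("angles must be strictly increasing in [0, 2*pi)")
        if sorted(self.pin_permutation) != list(range(self.n_electrodes)):
            raise ValueError("pin_permutation must be a bijection on electrode indices")

    @classmethod
    def equispaced(cls, n: int = 8) -> "ElectrodeLayout":
        """Equispaced ring, electrode 1 at angle 0, identity pin map."""
        if n < 4:
            raise ValueError("need at least 4 electrodes")
        return cls(
            n_electrodes=n,
            angles=tuple(2 * np.pi * k / n for k in range(n)),
            pin_permutation=tuple(range(n)),
        )


@dataclass(frozen=True)
class InjectionPattern:
    """Ordered drive pairs, each with its ordered measurement pairs."""

    entries: tuple[tuple[tuple[int, int], tuple[tuple[int, int], ...]], ...]

    @property
    def n_drives(self) -> int:
        return len(self.entries)

    @property
    def n_measures_per_drive(self) -> int:
        return len(self.entries[0][1])

    @property
    def n_measurements(self) -> int:
        return sum(len(m) for _, m in self.entries)


@dataclass(frozen=True)
class Frame:
    """One protocol cycle of RMS differential voltages (drive x measure)."""

    values: np.ndarray  # shape (n_drives, n_measures), volts
    label: str = "inhomogeneous"  # "homogeneous" for the reference frame
    index: int = 0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("frame values must be a 2-D matrix")
        if not np.all(np.isfinite(v)) or np.any(v < 0):
            raise ValueError("frame entries must be finite and non-negative")
        object.__setattr__(self, "values", v)
        if self.label not in ("homogeneous", "inhomogeneous"):
            raise ValueError("label must be 'homogeneous' or 'inhomogeneous'")

    @property
    def flat(self) -> np.ndarray:
        """Row-major 40-vector view used by the reconstruction."""
        return self.values.reshape(-1)


@dataclass(frozen=True)
class NoiseModel:
    """Additive measurement noise plus a slow per-slot drift.

    ``additive_sd`` is the standard deviation of zero-mean Gaussian noise on
    every measurement (volts); ``drift_rate`` is the per-slot step size of a
    slow random-walk drift accumulated across a frame's measurement slots,
    emulating the settling drift seen at long multiplexer switching times
    (its variance grows with the slot index).
    """

    additive_sd: float = 0.0
    drift_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.additive_sd < 0:
            raise ValueError("additive_sd must be >= 0")


def adjacent_pattern(layout: ElectrodeLayout) -> InjectionPattern:
    """Adjacent protocol on the layout's ring (0-based electrode indices).

    Drive pairs are consecutive electrodes ``(i, i+1 mod n)``; for each
    drive the measurement pairs are the consecutive pairs not containing a
    drive electrode, walked in ring order — ``n-3`` of them, ``n*(n-3)``
    measurements in total.
    """
    n = layout.n_electrodes
    if n < 4:
        raise ValueError("adjacent pattern needs at least 4 electrodes")
    entries = []
    for i in range(n):
        drive = (i, (i + 1) % n)
        measures = tuple(
            ((i + 2 + j) % n, (i + 3 + j) % n) for j in range(n - 3)
        )
        entries.append((drive, measures))
    return InjectionPattern(entries=tuple(entries))


def differential_voltage(v1: float, v2: float) -> float:
    """Output of the unity-gain differential meter: ``V2 - V1``."""
    return v2 - v1


def acquire_frames(
    true_voltages: np.ndarray,
    noise: NoiseModel,
    n_frames: int,
    shape: tuple[int, int] = (8, 5),
    label: str = "inhomogeneous",
    start_index: int = 0,
) -> list[Frame]:
    """Simulate repeated frame captures of a fixed scenario.

    Each frame is truth plus i.i.d. Gaussian noise plus a slow random-walk
    drift accumulated across the frame's measurement slots (row-major
    order).  Negative results are clipped at zero, matching the RMS
    demodulator, and the output is deterministic for a fixed ``noise.seed``.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    truth = np.asarray(true_voltages, dtype=float).reshape(-1)
    if truth.size != shape[0] * shape[1]:
        raise ValueError(f"expected {shape[0] * shape[1]} voltages, got {truth.size}")
    rng = np.random.default_rng(noise.seed)
    frames = []
    for f in range(n_frames):
        values = truth.copy()
        if noise.drift_rate > 0:
            values = values + np.cumsum(rng.normal(0.0, noise.drift_rate, truth.size))
        if noise.additive_sd > 0:
            values = values + rng.normal(0.0, noise.additive_sd, truth.size)
        frames.append(
            Frame(
                values=np.clip(values, 0.0, None).reshape(shape),
                label=label,
                index=start_index + f,
            )
        )
    return frames


def write_frames(frames: list[Frame], directory: str | Path) -> list[Path]:
    """Write frames as ``Frame<k>.txt`` files; the first must be the reference."""
    if not frames:
        raise ValueError("no frames to write")
    if frames[0].label != "homogeneous":
        raise ValueError("first frame must be the homogeneous reference (Frame0)")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for k, frame in enumerate(frames):
        path = directory / f"Frame{k}.txt"
        np.savetxt(path, frame.values, fmt="%.9e")
        paths.append(path)
    return paths


def _parse_frame_file(path: Path) -> np.ndarray:
    rows = []
    width = None
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue  # blank lines tolerated
        try:
            row = [float(tok) for tok in line.split()]
        except ValueError as exc:
            raise FrameFormatError(f"{path.name}, line {lineno}: {exc}") from None
        if width is None:
            width = len(row)
        elif len(row) != width:
            raise FrameFormatError(
                f"{path.name}, line {lineno}: expected {width} columns, got {len(row)}"
            )
        rows.append(row)
    if not rows:
        raise FrameFormatError(f"{path.name}: no data rows")
    return np.asarray(rows, dtype=float)


def read_frames(
    directory: str | Path, shape: tuple[int, int] = (8, 5)
) -> list[Frame]:
    """Read a directory of ``Frame<k>.txt`` files, sorted by index.

    ``Frame0`` is required and labeled homogeneous.  Files holding a flat
    vector of the right length are accepted and reshaped, but the matrix
    layout is the preferred dialect.
    """
    directory = Path(directory)
    pattern = re.compile(r"Frame(\d+)\.txt$")
    found = {}
    for path in directory.glob("Frame*.txt"):
        m = pattern.fullmatch(path.name)
        if m:
            found[int(m.group(1))] = path
    if 0 not in found:
        raise FileNotFoundError(
            f"reference frame required: no Frame0.txt in {directory}"
        )
    n_expected = shape[0] * shape[1]
    frames = []
    for index in sorted(found):
        matrix = _parse_frame_file(found[index])
        if matrix.shape == shape:
            values = matrix
        elif matrix.size == n_expected and 1 in matrix.shape:
            values = matrix.reshape(shape)
        else:
            raise FrameFormatError(
                f"{found[index].name}: expected {shape[0]}x{shape[1]} matrix, "
                f"got {matrix.shape[0]}x{matrix.shape[1]}"
            )
        frames.append(
            Frame(
                values=values,
                label="homogeneous" if index == 0 else "inhomogeneous",
                index=index,
            )
        )
    return frames
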