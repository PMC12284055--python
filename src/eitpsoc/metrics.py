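"""Channel statistics over repeated frames and the global-impedance index.

Per measurement channel ``i`` over repeated frames ``j``:

* ``SNR_i = 20*log10(|mean_j m(i,j)| / sd_j m(i,j))`` in dB (sd is the
  square root of the unbiased variance; a variance-denominator variant is
  exposed for comparison),
* ``Ac_i = (1 - |(mean_j m(i,j) - m_i^T)/m_i^T|) * 100`` percent against a
  true value ``m^T`` (in simulation, the noise-free forward voltages).

The global impedance index of a sequence of reconstructed frames is the
pixel sum of each image; its reciprocal magnitude ``|GI|^-1`` tracks
inclusion (fluid) volume.  Both per-frame values and the cumulative sum
over frames are reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .acquisition import Frame
from .reconstruction import PixelImage

__all__ = ["ChannelStats", "GISeries", "snr_stats", "accuracy_stats", "global_impedance"]


@dataclass(frozen=True)
class ChannelStats:
    """Per-channel statistics of a stack of repeated frames."""

    mean: np.ndarray  # volts, per channel
    dispersion: np.ndarray  # volts (sd unless variance denominator chosen)
    snr_db: np.ndarray | None = None
    accuracy_pct: np.ndarray | None = None

    def summary(self, which: str = "snr_db") -> dict[str, float]:
        """Mean/median/min/max over channels of ``snr_db`` or ``accuracy_pct``."""
        values = getattr(self, which)
        if values is None:
            raise ValueError(f"{which} was not computed")
        finite = values[np.isfinite(values)]
        if finite.size == 0:
            return {k: float("inf") for k in ("mean", "median", "min", "max")}
        return {
            "mean": float(np.mean(finite)),
            "median": float(np.median(finite)),
            "min": float(np.min(finite)),
            "max": float(np.max(finite)),
        }


def _channel_matrix(frames: list[Frame]) -> np.ndarray:
    m = np.stack([f.flat for f in frames], axis=1)  # (n_channels, n_frames)
    return m


def snr_stats(frames: list[Frame], denominator: str = "sd") -> ChannelStats:
    """Per-channel SNR (dB) over repeated frames.

    ``denominator`` selects sd (default) or raw variance in the log ratio.
    Channels with zero dispersion get a ``+inf`` sentinel and a warning.
    """
    if len(frames) < 2:
        raise ValueError("need at least 2 frames for SNR")
    if denominator not in ("sd", "variance"):
        raise ValueError("denominator must be 'sd' or 'variance'")
    m = _channel_matrix(frames)
    mean = m.mean(axis=1)
    var = m.var(axis=1, ddof=1)
    disp = np.sqrt(var) if denominator == "sd" else var
    snr = np.full(mean.shape, np.inf)
    nonzero = disp > 0
    if not np.all(nonzero):
        warnings.warn("zero dispersion on some channels; SNR reported as +inf")
    snr[nonzero] = 20.0 * np.log10(np.abs(mean[nonzero]) / disp[nonzero])
    return ChannelStats(mean=mean, dispersion=np.sqrt(var), snr_db=snr)


def accuracy_stats(frames: list[Frame], truth: np.ndarray) -> ChannelStats:
    """Per-channel accuracy (%) of the frame means against a truth vector."""
    if not frames:
        raise ValueError("no frames")
    truth = np.asarray(truth, dtype=float).reshape(-1)
    if np.any(truth == 0):
        raise ValueError("truth vector contains zeros")
    m = _channel_matrix(frames)
    if m.shape[0] != truth.size:
        raise ValueError("truth length does not match channel count")
    mean = m.mean(axis=1)
    acc = (1.0 - np.abs((mean - truth) / truth)) * 100.0
    return ChannelStats(
        mean=mean,
        dispersion=m.std(axis=1, ddof=1) if m.shape[1] > 1 else np.zeros_like(mean),
        accuracy_pct=acc,
    )


@dataclass(frozen=True)
class GISeries:
    """Global-impedance index of a reconstructed frame sequence."""

    frame_sums: np.ndarray  # pixel sum per frame
    gi_total: float  # cumulative sum over frames and pixels
    inv_frame: np.ndarray  # |GI|^-1 per frame (nan where the sum is zero)
    inv_total: float  # |GI_total|^-1 (nan when zero)


def global_impedance(images: list[PixelImage]) -> GISeries:
    """Pixel sums per frame, their cumulative total, and ``|GI|^-1``."""
    if not images:
        raise ValueError("need at least one image")
    sums = np.array([float(img.values.sum()) for img in images])
    total = float(sums.sum())
    with np.errstate(divide="ignore"):
        inv_frame = np.where(sums != 0, 1.0 / np.abs(sums), np.nan)
    inv_total = 1.0 / abs(total) if total != 0 else float("nan")
    return GISeries(
        frame_sums=sums, gi_total=total, inv_frame=inv_frame, inv_total=inv_total
    )
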