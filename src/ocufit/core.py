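"""Core data model for time-resolved fundus fluorescence (FLIO/FLIM) data.

The universal input is a TCSPC photon-count cube: for every image pixel a
histogram of photon arrival times relative to the excitation laser pulse.
Alongside it live the measured instrument response function (IRF), an
optionally measured crystalline-lens decay, and the per-pixel result maps
produced by decay fitting.

Units are fixed internally: lifetimes and time shifts in picoseconds,
the laser repetition period in nanoseconds, pixel pitch in micrometers.
Conversions happen only at I/O boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "OcufitError",
    "MetadataError",
    "FormatError",
    "DegenerateIRFError",
    "DegenerateDofError",
    "TimeAxis",
    "TCSPCCube",
    "IRFCurve",
    "LensDecay",
    "FitResultMaps",
    "SubjectRecord",
    "StudySet",
    "repetition_period_ns",
    "SPEED_OF_LIGHT_M_PER_S",
]

#: Speed of light used for optical path-length to time-shift conversion.
SPEED_OF_LIGHT_M_PER_S = 3.0e8


class OcufitError(Exception):
    """Base class for all package errors."""


class MetadataError(OcufitError):
    """Required acquisition metadata is missing or inconsistent."""


class FormatError(OcufitError):
    """On-disk data violates the format contract (e.g. negative counts)."""


class DegenerateIRFError(OcufitError):
    """An IRF or lens curve without any positive value."""


class DegenerateDofError(OcufitError):
    """Reduced chi-square requested with no positive degrees of freedom."""


def repetition_period_ns(rep_rate_mhz: float) -> float:
    """Laser repetition period t_R (ns) from the pulse repetition rate (MHz).

    An 80 MHz source yields t_R = 12.5 ns.
    """
    if rep_rate_mhz <= 0:
        raise ValueError("repetition rate must be positive")
    return 1e3 / rep_rate_mhz


@dataclass(frozen=True)
class TimeAxis:
    """Discretization of the inter-pulse interval into TCSPC time channels.

    Parameters
    ----------
    n_channels:
        Number of time bins m of the photon histogram.
    channel_width_ps:
        Width of one time channel in picoseconds.
    rep_period_ns:
        Laser repetition period t_R in nanoseconds.  Channel j covers
        [j*dt, (j+1)*dt); model curves are evaluated at channel centers.
    """

    n_channels: int = 1024
    channel_width_ps: float = 12.2
    rep_period_ns: float = 12.5

    def __post_init__(self) -> None:
        if self.n_channels < 1:
            raise ValueError("n_channels must be a positive integer")
        if self.channel_width_ps <= 0:
            raise ValueError("channel_width_ps must be positive")
        span = self.n_channels * self.channel_width_ps
        if span > self.rep_period_ns * 1e3 + 0.5 * self.channel_width_ps:
            raise ValueError(
                "time axis spans more than the repetition period: "
                f"{span:.1f} ps > {self.rep_period_ns * 1e3:.1f} ps"
            )

    @property
    def rep_period_ps(self) -> float:
        return self.rep_period_ns * 1e3

    def centers_ps(self) -> np.ndarray:
        """Channel-center times (ps)."""
        return (np.arange(self.n_channels) + 0.5) * self.channel_width_ps

    def extended(self, factor: int) -> "TimeAxis":
        """Time axis with `factor` times as many channels (same width).

        Used for incomplete-decay folding, where the model is evaluated over
        several repetition periods before shifted copies are summed.
        """
        if factor < 1:
            raise ValueError("factor must be >= 1")
        return TimeAxis(
            n_channels=self.n_channels * factor,
            channel_width_ps=self.channel_width_ps,
            rep_period_ns=self.rep_period_ns * factor,
        )


def _as_counts(a: np.ndarray) -> np.ndarray:
    arr = np.asarray(a)
    if not np.issubdtype(arr.dtype, np.number):
        raise FormatError("counts must be numeric")
    if np.any(arr < 0):
        raise FormatError("negative photon counts")
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.all(np.mod(arr, 1) == 0):
            raise FormatError("photon counts must be integers")
    return arr.astype(np.int64)


@dataclass
class TCSPCCube:
    """Per-spectral-channel 3-D photon-count histogram (row, col, time)."""

    counts: np.ndarray
    time: TimeAxis
    spectral_range_nm: tuple[float, float] = (498.0, 560.0)
    pixel_pitch_um: float = 59.0
    channel_id: int = 1

    def __post_init__(self) -> None:
        self.counts = _as_counts(self.counts)
        if self.counts.ndim != 3:
            raise FormatError("counts must be 3-D (row, col, time)")
        if self.counts.shape[2] != self.time.n_channels:
            raise MetadataError(
                f"cube has {self.counts.shape[2]} time channels but the time "
                f"axis declares {self.time.n_channels}"
            )
        if self.pixel_pitch_um <= 0:
            raise MetadataError("pixel_pitch_um must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.counts.shape

    def intensity(self) -> np.ndarray:
        """Total photons per pixel (the autofluorescence intensity image)."""
        return self.counts.sum(axis=2)

    def total_photons(self) -> int:
        return int(self.counts.sum())


@dataclass
class IRFCurve:
    """Measured instrument response on a cube's time axis."""

    values: np.ndarray
    time: TimeAxis

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size != self.time.n_channels:
            raise MetadataError("IRF length must match the time axis")
        if np.any(self.values < 0):
            raise FormatError("IRF values must be non-negative")
        if not np.any(self.values > 0):
            raise DegenerateIRFError("IRF has no positive value")

    def normalized(self) -> np.ndarray:
        """Unit-sum IRF so that fitted amplitudes keep their photon meaning."""
        return self.values / self.values.sum()


@dataclass
class LensDecay:
    """Separately measured crystalline-lens fluorescence decay.

    Already an IRF-broadened physical signal; it enters the lens-corrected
    model as a scaled, time-shifted additive term.
    """

    values: np.ndarray
    time: TimeAxis

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size != self.time.n_channels:
            raise MetadataError("lens curve length must match the time axis")
        if np.any(self.values < 0):
            raise FormatError("lens decay values must be non-negative")
        if not np.any(self.values > 0):
            raise DegenerateIRFError("lens decay has no positive value")

    def normalized(self) -> np.ndarray:
        return self.values / self.values.sum()


@dataclass
class FitResultMaps:
    """Per-pixel fitted parameter maps plus fit diagnostics.

    `maps` holds one 2-D float array per quantity, keyed by name:
    amplitudes ``alpha1..k``, lifetimes ``tau1..k`` (ps), shifts ``tc1..k``
    (ps), ``beta``, ``alpha_lens``, ``tc_lens``, ``background``, the figure
    of merit ``chi2``, the amplitude-weighted mean lifetime ``tau_m``, the
    adaptive binning ``radius`` and a ``converged`` flag map.
    """

    maps: dict[str, np.ndarray]
    artifact_intervals: list[tuple[int, int]] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {m.shape for m in self.maps.values()}
        if len(shapes) > 1:
            raise FormatError(f"result maps have inconsistent shapes: {shapes}")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.maps.values())).shape

    def lifetime_names(self) -> list[str]:
        return sorted(k for k in self.maps if k.startswith("tau") and k != "tau_m")

    def __getitem__(self, key: str) -> np.ndarray:
        return self.maps[key]


@dataclass
class SubjectRecord:
    subject_id: str
    group: str
    results: FitResultMaps
    roi_mask: np.ndarray

    def __post_init__(self) -> None:
        self.roi_mask = np.asarray(self.roi_mask, dtype=bool)
        if self.roi_mask.shape != self.results.shape:
            raise FormatError("ROI mask shape does not match result maps")


@dataclass
class StudySet:
    """Collection of subjects' result maps for a two-group comparison."""

    subjects: list[SubjectRecord]

    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.subjects:
            seen.setdefault(s.group, None)
        return list(seen)

    def by_group(self, group: str) -> list[SubjectRecord]:
        return [s for s in self.subjects if s.group == group]

    def validate_two_groups(self) -> tuple[str, str]:
        g = self.groups()
        if len(g) != 2:
            raise ValueError(f"expected exactly two groups, found {g}")
        for name in g:
            if len(self.by_group(name)) < 2:
                raise ValueError(f"group {name!r} needs at least 2 subjects")
        return g[0], g[1]
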