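"""Core value types shared across the pipeline.

All physical quantities carry SI-derived units noted per field: times in
seconds, lengths in micrometres, volumes in μm³, areas in μm², photon counts
dimensionless. Containers are plain dataclasses that validate on
construction; heavy numerics live in the operation modules.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

__all__ = [
    "FcsParams",
    "IntensityTrace",
    "CorrelationCurve",
    "FitResult",
    "NucleusImage",
    "NucleusMask",
    "MorphometryRecord",
]

_FRACTION_ATOL = 1e-9


@dataclass(frozen=True)
class FcsParams:
    """Parameter set of the diffusion + two-binding-population ACF model.

    G(tau) = 1/(2^{3/2} N) * [ f_D (1+tau/tau_D)^{-1} (1+tau/(omega^2 tau_D))^{-1/2}
                               + f_short exp(-tau/tau_short)
                               + f_long  exp(-tau/tau_long) ]

    Attributes
    ----------
    n_molecules : float
        Mean number of fluorescent molecules in the effective confocal
        volume (N > 0).
    f_diff, f_short, f_long : float
        Population fractions of freely diffusing, short-lived bound and
        long-lived bound molecules; constrained to the simplex
        (each in [0, 1], summing to 1).
    tau_diff : float
        Characteristic diffusion time through the observation volume (s).
    omega : float
        Axial/radial waist ratio w_z / w_r of the observation volume.
    tau_short, tau_long : float
        Residence times on short- and long-lived chromatin targets (s),
        with tau_short < tau_long. Their reciprocals are the dissociation
        rates k_off.
    """

    n_molecules: float
    f_diff: float
    f_short: float
    f_long: float
    tau_diff: float
    omega: float
    tau_short: float
    tau_long: float

    def __post_init__(self) -> None:
        if not self.n_molecules > 0:
            raise ValueError("n_molecules must be > 0")
        if not self.omega > 0:
            raise ValueError("omega must be > 0")
        for name in ("tau_diff", "tau_short", "tau_long"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        fracs = (self.f_diff, self.f_short, self.f_long)
        if any(f < -_FRACTION_ATOL or f > 1 + _FRACTION_ATOL for f in fracs):
            raise ValueError("fractions must lie in [0, 1]")
        if abs(sum(fracs) - 1.0) > 1e-6:
            raise ValueError("fractions must sum to 1 (simplex constraint)")
        if self.tau_short >= self.tau_long:
            raise ValueError("tau_short must be < tau_long")

    @property
    def k_off_short(self) -> float:
        """Dissociation rate of the short-lived sites, 1/tau_short (1/s)."""
        return 1.0 / self.tau_short

    @property
    def k_off_long(self) -> float:
        """Dissociation rate of the long-lived sites, 1/tau_long (1/s)."""
        return 1.0 / self.tau_long

    def replace(self, **kw) -> "FcsParams":
        return replace(self, **kw)


@dataclass
class IntensityTrace:
    """Binned photon counts from one single-point FCS acquisition."""

    counts: np.ndarray  # non-negative integers, one entry per time bin
    bin_width: float  # s
    label: str = ""
    cell_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 1 or self.counts.size < 2:
            raise ValueError("counts must be a 1-D sequence of length >= 2")
        if not self.bin_width > 0:
            raise ValueError("bin_width must be > 0")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if not np.issubdtype(self.counts.dtype, np.integer):
            rounded = np.rint(self.counts)
            if not np.allclose(self.counts, rounded):
                raise ValueError("counts must be integral")
            self.counts = rounded.astype(np.int64)

    @property
    def duration(self) -> float:
        """Total acquisition time in seconds."""
        return self.counts.size * self.bin_width

    @property
    def times(self) -> np.ndarray:
        """Bin start times in seconds."""
        return np.arange(self.counts.size) * self.bin_width


@dataclass
class CorrelationCurve:
    """Normalized autocorrelation G(tau) on a strictly increasing lag grid."""

    lags: np.ndarray  # s, strictly increasing, > 0
    g: np.ndarray  # dimensionless
    sd: Optional[np.ndarray] = None  # per-lag standard deviation, >= 0
    n_traces_averaged: int = 1
    label: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        if self.lags.ndim != 1 or self.lags.size == 0:
            raise ValueError("lag grid must be non-empty and 1-D")
        if self.lags.size != self.g.size:
            raise ValueError("lags and G values must have equal length")
        if np.any(self.lags <= 0) or np.any(np.diff(self.lags) <= 0):
            raise ValueError("lags must be strictly increasing and positive")
        if not np.all(np.isfinite(self.g)):
            raise ValueError("G values must be finite")
        if self.sd is not None:
            self.sd = np.asarray(self.sd, dtype=float)
            if self.sd.size != self.lags.size or np.any(self.sd < 0):
                raise ValueError("per-lag SD must match lags and be >= 0")
        if self.n_traces_averaged < 1:
            raise ValueError("n_traces_averaged must be >= 1")


@dataclass
class FitResult:
    """Outcome of fitting the ACF model to one correlation curve."""

    params: FcsParams
    se: dict  # per-parameter standard errors, keys match FcsParams fields
    rss: float  # residual sum of squares (weighted)
    converged: bool
    n_restarts_used: int = 1

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.se.values() if np.isfinite(v)):
            raise ValueError("standard errors must be >= 0")

    @property
    def k_off_short(self) -> float:
        return self.params.k_off_short

    @property
    def k_off_long(self) -> float:
        return self.params.k_off_long

    def as_row(self) -> dict:
        """Flatten into one table row (per-cell result record)."""
        p = self.params
        row = {
            "n_molecules": p.n_molecules,
            "f_diff": p.f_diff,
            "f_short": p.f_short,
            "f_long": p.f_long,
            "tau_diff": p.tau_diff,
            "tau_short": p.tau_short,
            "tau_long": p.tau_long,
            "omega": p.omega,
            "k_off_short": p.k_off_short,
            "k_off_long": p.k_off_long,
            "rss": self.rss,
            "converged": self.converged,
            "n_restarts_used": self.n_restarts_used,
        }
        for key, val in self.se.items():
            row[f"se_{key}"] = val
        return row


@dataclass
class NucleusImage:
    """A 3-D confocal stack with physical voxel sizes.

    The intensity grid is indexed (z, y, x); ``voxel_size`` is
    (dx, dy, dz) in micrometres.
    """

    data: np.ndarray
    voxel_size: tuple  # (dx, dy, dz) in um
    channel: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("image must be 3-D (z, y, x)")
        if min(self.data.shape) < 8:
            raise ValueError("image must have >= 8 voxels per axis")
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be three positive numbers")
        if not np.all(np.isfinite(self.data)) or np.any(self.data < 0):
            raise ValueError("intensities must be finite and >= 0")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in μm³."""
        dx, dy, dz = self.voxel_size
        return dx * dy * dz


@dataclass
class NucleusMask:
    """Integer label grid aligned with a NucleusImage (0 = background)."""

    labels: np.ndarray
    voxel_size: tuple  # (dx, dy, dz) in um

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("mask must be 3-D (z, y, x)")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integers")
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be three positive numbers")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)

    @property
    def label_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]

    @property
    def voxel_volume(self) -> float:
        dx, dy, dz = self.voxel_size
        return dx * dy * dz


@dataclass
class MorphometryRecord:
    """Per-nucleus shape descriptors."""

    nucleus_id: int
    volume: float  # um^3
    surface_area: float  # um^2
    sphericity: float  # dimensionless, 1 for a perfect sphere
    touches_border: bool = False
    condition: str = ""

    def __post_init__(self) -> None:
        if not self.volume > 0:
            raise ValueError("volume must be > 0")
        if not self.surface_area > 0:
            raise ValueError("surface area must be > 0")
        if not self.sphericity > 0:
            raise ValueError("sphericity must be > 0")

    def as_row(self) -> dict:
        return {
            "nucleus_id": self.nucleus_id,
            "condition": self.condition,
            "volume_um3": self.volume,
            "area_um2": self.surface_area,
            "sphericity": self.sphericity,
            "border_flag": self.touches_border,
        }
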