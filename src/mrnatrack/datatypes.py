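"""Core containers shared across the analysis modules.

Conventions used throughout the package:

* track coordinates are in micrometres, track time in seconds;
* intensity time courses use minutes;
* images are 2-D ``numpy`` arrays indexed ``[row, col]`` = ``[y, x]``
  with a pixel size in nanometres (pixel-centre, 0-based coordinates);
* the anterior reference frame is given by a point on the anterior
  cortex and a unit vector pointing from the anterior into the oocyte
  (towards the posterior), so the *anterior* direction is its negation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np

__all__ = [
    "AnteriorAxis",
    "Track",
    "TrackSummary",
    "DirectionalityResult",
    "MobileFractionResult",
    "IntensitySeries",
    "BleachModel",
    "RecoveryFit",
    "CurveComparison",
    "StedImage",
    "LorentzianFit",
    "SpotFit",
    "PopulationStats",
    "CCFResult",
    "QpcrSample",
    "ParameterError",
]


class ParameterError(ValueError):
    """Raised when a user-supplied parameter violates its contract."""


@dataclass(frozen=True)
class AnteriorAxis:
    """Reference frame for 'anterior' measurements.

    ``origin`` is a point on the anterior cortex (μm); ``posterior_unit``
    is the unit vector pointing from the anterior cortex into the oocyte.
    The signed distance of a point ``p`` from the anterior is
    ``(p - origin) · posterior_unit``; a displacement is anterior-directed
    when its projection on ``posterior_unit`` is negative.
    """

    origin: tuple[float, float] = (0.0, 0.0)
    posterior_unit: tuple[float, float] = (1.0, 0.0)

    def __post_init__(self) -> None:
        n = float(np.hypot(*self.posterior_unit))
        if not np.isclose(n, 1.0, atol=1e-8):
            raise ParameterError(f"posterior_unit must have norm 1, got {n}")

    @property
    def anterior_unit(self) -> np.ndarray:
        return -np.asarray(self.posterior_unit, dtype=float)

    def distance_from_anterior(self, point: Sequence[float]) -> float:
        d = np.asarray(point, dtype=float) - np.asarray(self.origin, dtype=float)
        return float(d @ np.asarray(self.posterior_unit, dtype=float))

    def anterior_component(self, vector: Sequence[float]) -> float:
        """Projection of a displacement vector on the anterior direction."""
        return float(np.asarray(vector, dtype=float) @ self.anterior_unit)


@dataclass
class Track:
    """Time-ordered 2-D positions of one moving RNA particle."""

    track_id: str
    t: np.ndarray  # seconds
    x: np.ndarray  # μm
    y: np.ndarray  # μm
    oocyte_id: str = "oocyte0"
    movie_id: str = "movie0"
    genotype: str = ""

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (self.t.shape == self.x.shape == self.y.shape):
            raise ParameterError("t, x, y must have equal length")
        if self.t.size < 2:
            raise ParameterError(f"track {self.track_id!r} needs >= 2 frames")
        if np.any(np.diff(self.t) <= 0):
            raise ParameterError(f"track {self.track_id!r} has non-increasing time")

    @property
    def n_frames(self) -> int:
        return int(self.t.size)

    @property
    def positions(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])


@dataclass
class TrackSummary:
    track_id: str
    mean_speed: float  # μm/s
    track_distance: float  # μm, summed step lengths
    direction_angle: float  # degrees, initial->final vector vs +x axis
    direction2: Literal["anterior", "posterior"]
    direction3: Literal["anterior", "posterior", "lateral"]
    initial_distance_from_anterior: float  # μm
    anterior_displacement_rate: float  # μm/s
    n_reversals: int
    oocyte_id: str = "oocyte0"
    movie_id: str = "movie0"
    genotype: str = ""


@dataclass
class DirectionalityResult:
    n_tracks: int
    n_anterior: int
    n_posterior: int
    counts3: dict  # anterior/posterior/lateral counts
    bin_edges_um: list
    counts_per_bin: list  # one (n_anterior, n_posterior) pair per distance bin
    windchart_bin_deg: float
    windchart_edges: np.ndarray
    windchart_freq: np.ndarray
    binomial_p: float
    wilcoxon_net_p: float


@dataclass
class MobileFractionResult:
    mobile_fraction: float
    n_particles: int
    n_mobile: int
    window_s: float
    move_threshold_um: float


@dataclass
class IntensitySeries:
    """Background-subtracted mean ROI intensity over time (minutes)."""

    t: np.ndarray  # min
    I: np.ndarray  # a.u.
    kind: Literal["frap", "photoconversion", "control_fixed", "control_nursecell"] = "frap"
    sample_id: str = "sample0"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        if self.t.size == 0:
            raise ParameterError("intensity series needs >= 1 time point")
        if self.t.shape != self.I.shape:
            raise ParameterError("t and I must have equal length")
        if np.any(np.diff(self.t) <= 0):
            raise ParameterError("time points must be strictly increasing")
        if not np.all(np.isfinite(self.I)):
            raise ParameterError("intensities must be finite")

    def replace(self, I: np.ndarray) -> "IntensitySeries":
        return IntensitySeries(t=self.t.copy(), I=np.asarray(I, dtype=float),
                               kind=self.kind, sample_id=self.sample_id)


@dataclass
class BleachModel:
    """Acquisition-photobleaching model I(t) = I0 * exp(-p t)."""

    I0: float
    p: float  # min^-1

    def __post_init__(self) -> None:
        if self.p < 0:
            raise ParameterError("bleach rate p must be >= 0")

    def predict(self, t: np.ndarray) -> np.ndarray:
        return self.I0 * np.exp(-self.p * np.asarray(t, dtype=float))


@dataclass
class RecoveryFit:
    """Fitted parameters of a recovery/decay time course.

    For the bi-exponential form the mobile signal splits into a fast
    nonspecific component (amplitude ``C_NS``, half-time ``tau_NS``,
    held fixed during fitting) and a slow RNA-specific component
    (``C_RNA``, ``tau_RNA``).  The single-exponential form reports a
    single mobile fraction ``F_MOB`` with half-time ``tau``.
    """

    mode: Literal["frap", "photoconversion"]
    F_IM: float
    F_MOB: Optional[float] = None
    C_NS: Optional[float] = None
    C_RNA: Optional[float] = None
    tau: Optional[float] = None  # min, single-exponential half-time
    tau_NS: Optional[float] = None  # min, fixed input
    tau_RNA: Optional[float] = None  # min
    ss_resid: float = np.nan
    r2: float = np.nan
    n_points: int = 0
    converged: bool = True

    def predict(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        ln2 = np.log(2.0)
        if self.C_NS is not None:  # bi-exponential
            ns = self.C_NS * np.exp(-ln2 * t / self.tau_NS)
            rna = self.C_RNA * np.exp(-ln2 * t / self.tau_RNA)
            if self.mode == "frap":
                return 1.0 - self.F_IM - ns - rna
            return self.F_IM + ns + rna
        mob = self.F_MOB * np.exp(-ln2 * t / self.tau)
        if self.mode == "frap":
            return 1.0 - self.F_IM - mob
        return self.F_IM + mob


@dataclass
class CurveComparison:
    F: float
    df_num: int
    df_den: int
    p: float


@dataclass
class StedImage:
    """Single-channel 2-D intensity grid with physical pixel size."""

    pixels: np.ndarray  # [row, col] a.u.
    pixel_size: float  # nm
    axis: Optional[AnteriorAxis] = None  # in pixel coordinates if given

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ParameterError("image must be a non-empty 2-D array")
        if self.pixel_size <= 0:
            raise ParameterError("pixel_size must be > 0")
        if not np.all(np.isfinite(self.pixels)):
            raise ParameterError("image intensities must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class LorentzianFit:
    """1-D Lorentzian B + A / (1 + ((x - center)/gamma)^2) fitted to a profile."""

    center: float  # px, relative to profile start
    gamma: float  # px, half-width at half-maximum
    amplitude: float  # a.u.
    baseline: float  # a.u.
    fwhm: float  # nm (2 * gamma * pixel_size)
    r2: float
    converged: bool = True


@dataclass
class SpotFit:
    x0: int  # px (column)
    y0: int  # px (row)
    fit_x: Optional[LorentzianFit] = None
    fit_y: Optional[LorentzianFit] = None
    diameter: float = np.nan  # nm, mean of the two FWHMs
    summed_fluorescence: float = np.nan  # a.u.
    distance_from_anterior: float = np.nan  # μm
    accepted: bool = False
    rejection_reason: Literal["none", "low_r2", "axis_ratio", "edge", "dense"] = "none"
    oocyte_id: str = "oocyte0"


@dataclass
class PopulationStats:
    n: int
    mean_size: float  # nm
    sem_size: float
    mean_summed_fluorescence: float
    sem_summed_fluorescence: float
    mean_nn_distance: float = np.nan  # nm
    size_vs_distance_p: float = np.nan
    fluorescence_vs_distance_p: float = np.nan


@dataclass
class CCFResult:
    shifts: np.ndarray  # px
    r: np.ndarray  # Pearson coefficient per shift (NaN where undefined)
    r_zero: float
    peak_shift: int
    costes_p: float = np.nan
    n_randomizations: int = 0


@dataclass(frozen=True)
class QpcrSample:
    """Threshold cycles for a gene of interest and an internal control."""

    CT_gene: float
    CT_internal: float
    label: str = ""

    def __post_init__(self) -> None:
        for v in (self.CT_gene, self.CT_internal):
            if not (np.isfinite(v) and v > 0):
                raise ParameterError("CT values must be positive and finite")

    @property
    def delta_ct(self) -> float:
        return self.CT_gene - self.CT_internal
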