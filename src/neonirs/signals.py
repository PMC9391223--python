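"""Core signal containers and the modified Beer-Lambert constants.

All time series are stored channel-major as numpy arrays at a common
sampling rate (10 Hz by default).  Concentrations are in umol/l, optical
densities are dimensionless, intensities are in arbitrary device units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

WAVELENGTHS = (760, 850)  # nm, fixed order everywhere

__all__ = [
    "WAVELENGTHS", "MbllParams", "RawRecording",
    "OpticalDensitySeries", "HemoSeries",
]


@dataclass(frozen=True)
class MbllParams:
    """Extinction coefficients and pathlength factors for the 2x2 MBLL system.

    ``extinction`` is indexed [wavelength][chromophore] with wavelength order
    (760, 850) nm and chromophore order (HbO, Hb), units 1/(mM*cm).
    ``dpf`` is the differential pathlength factor per wavelength.  The device
    constants are not dictated by the analysis; the defaults below are
    conventional continuous-wave values and only forward/inverse consistency
    is ever asserted about them.
    """

    extinction: tuple[tuple[float, float], tuple[float, float]] = (
        (1.4866, 3.8437),   # 760 nm: (HbO, Hb)
        (2.5264, 1.7986),   # 850 nm
    )
    dpf: tuple[float, float] = (5.0, 5.0)
    log_base: float = 10.0

    def __post_init__(self) -> None:
        eps = np.asarray(self.extinction, dtype=float)
        if eps.shape != (2, 2):
            raise ValueError("extinction must be a 2x2 matrix")
        if abs(np.linalg.det(eps)) < 1e-12:
            raise ValueError("extinction matrix is singular")
        if any(d <= 0 for d in self.dpf):
            raise ValueError("dpf must be positive")
        if self.log_base not in (10.0, np.e) and self.log_base <= 1:
            raise ValueError("log_base must be > 1")

    @property
    def eps_matrix(self) -> np.ndarray:
        return np.asarray(self.extinction, dtype=float)


def _as_2d(a, name):
    a = np.asarray(a, dtype=float)
    if a.ndim != 2:
        raise ValueError(f"{name} must be 2-D (channel x time)")
    return a


@dataclass
class RawRecording:
    """Two-wavelength optical intensities for one subject/session.

    ``intensity`` has shape (n_channels, 2, n_samples) with wavelength order
    (760, 850) nm.
    """

    intensity: np.ndarray
    sampling_rate: float = 10.0
    dynamic_range: tuple[float, float] = (0.0, 2.0)
    subject_id: str = ""
    group: str = ""
    phase: str = ""
    session_kind: str = "test"

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 3 or self.intensity.shape[1] != 2:
            raise ValueError("intensity must have shape (channels, 2, time)")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensity values must be finite")

    @property
    def n_channels(self) -> int:
        return self.intensity.shape[0]

    @property
    def n_samples(self) -> int:
        return self.intensity.shape[2]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate


@dataclass
class OpticalDensitySeries:
    """Optical density changes, same layout as the source intensities."""

    od: np.ndarray  # (channels, 2, time)
    sampling_rate: float = 10.0
    mask: np.ndarray | None = None  # (channels, time) True = valid
    mask_reasons: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.od = np.asarray(self.od, dtype=float)
        if self.od.ndim != 3 or self.od.shape[1] != 2:
            raise ValueError("od must have shape (channels, 2, time)")
        if self.mask is None:
            self.mask = np.ones((self.od.shape[0], self.od.shape[2]), dtype=bool)


@dataclass
class HemoSeries:
    """Haemoglobin concentration changes, the pipeline's central signal type.

    ``hbo`` / ``hb`` are (n_channels, n_samples) arrays in umol/l.  ``mask``
    flags valid samples per channel; ``provenance`` records the processing
    steps that produced the series.
    """

    hbo: np.ndarray
    hb: np.ndarray
    sampling_rate: float = 10.0
    mask: np.ndarray | None = None
    channel_ids: list[int] | None = None
    provenance: list = field(default_factory=list)
    # per-trial validity from epoch-wise artifact rejection:
    # {"onsets": (n_events,) seconds, "valid": (n_events, n_channels) bool}
    trial_mask: dict | None = None

    def __post_init__(self) -> None:
        self.hbo = _as_2d(self.hbo, "hbo")
        self.hb = _as_2d(self.hb, "hb")
        if self.hbo.shape != self.hb.shape:
            raise ValueError("hbo and hb must have the same shape")
        if self.mask is None:
            self.mask = np.ones(self.hbo.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.hbo.shape:
                raise ValueError("mask must match hbo shape")
        if self.channel_ids is None:
            self.channel_ids = list(range(1, self.hbo.shape[0] + 1))

    @property
    def n_channels(self) -> int:
        return self.hbo.shape[0]

    @property
    def n_samples(self) -> int:
        return self.hbo.shape[1]

    def log_step(self, step: str, **params) -> None:
        self.provenance.append({"step": step, **params})

    def copy(self) -> "HemoSeries":
        return HemoSeries(
            self.hbo.copy(), self.hb.copy(), self.sampling_rate,
            self.mask.copy(), list(self.channel_ids),
            [dict(p) for p in self.provenance],
            None if self.trial_mask is None else
            {"onsets": self.trial_mask["onsets"].copy(),
             "valid": self.trial_mask["valid"].copy()},
        )
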