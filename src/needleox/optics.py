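"""Dual-wavelength tissue optics: optical-density changes, the modified
Beer-Lambert law (MBLL) forward model, and its closed-form inversion to
relative hemoglobin concentrations.

The MBLL describes light attenuation in a highly scattering medium. For a
wavelength lambda, the change in optical density is

    dOD(lambda) = -log10(Io / Ii)
                = [eps_HbO2(lambda) * [HbO2] + eps_Hb(lambda) * [Hb]] * L * B(lambda)

where Ii and Io are incident and penetrating intensity, eps are molar
extinction coefficients (base-10, cm^-1 M^-1), L is the source-detector
distance in cm, and B(lambda) is the dimensionless differential path length
factor (DPF) correcting L for scattering-lengthened photon paths. With
measurements at two wavelengths the 2x2 linear system is inverted in closed
form (Cramer's rule) to recover relative [HbO2] and [Hb]; total hemoglobin
and tissue oxygen saturation follow as [HbT] = [HbO2] + [Hb] and
StO2 = 100 * [HbO2] / [HbT].

Concentrations here are *relative* (arbitrary linear scale): the device is
not calibrated for absolute molarity, and L and B are nominal.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
from scipy.optimize import brentq

from .exceptions import (
    ConditioningError,
    DomainError,
    NotFoundError,
    RangeError,
)

__all__ = [
    "ExtinctionTable",
    "MeasurementGeometry",
    "HemoglobinState",
    "compute_delta_od",
    "forward_model",
    "invert_hemoglobin",
    "total_hemoglobin",
    "tissue_oxygen_saturation",
    "find_isosbestic",
    "calibrate_incident",
    "DEFAULT_WAVELENGTHS",
]

#: The two laser-diode wavelengths of the needle-tip probe, nm.
DEFAULT_WAVELENGTHS: tuple[float, float] = (690.0, 850.0)

#: Relative conditioning guard for the 2x2 extinction matrix:
#: reject when |det(A)| < DET_RTOL * ||A||_inf ** 2.
DET_RTOL = 1e-9


@dataclass(frozen=True)
class ExtinctionTable:
    """Wavelength-indexed molar extinction coefficients of HbO2 and Hb.

    Units are cm^-1 M^-1 under the base-10 (optical density) convention.
    Wavelengths must be strictly increasing and cover at least 650-1000 nm
    so that both probe wavelengths (690, 850 nm) are interpolable.
    """

    wavelengths: np.ndarray
    eps_hbo2: np.ndarray
    eps_hb: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        e1 = np.asarray(self.eps_hbo2, dtype=float)
        e2 = np.asarray(self.eps_hb, dtype=float)
        if wl.ndim != 1 or wl.size < 2:
            raise ValueError("extinction table needs >= 2 wavelength rows")
        if not (wl.shape == e1.shape == e2.shape):
            raise ValueError("extinction table columns have mismatched lengths")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if np.any(e1 <= 0) or np.any(e2 <= 0):
            raise ValueError("extinction coefficients must be positive")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "eps_hbo2", e1)
        object.__setattr__(self, "eps_hb", e2)

    @classmethod
    def from_csv(cls, path) -> "ExtinctionTable":
        """Read a delimited text table with columns wavelength_nm,
        eps_hbo2, eps_hb. Lines starting with ``#`` are comments."""
        wl, e1, e2 = [], [], []
        with open(path, newline="") as fh:
            rows = (r for r in fh if not r.lstrip().startswith("#"))
            reader = csv.DictReader(rows)
            for row in reader:
                wl.append(float(row["wavelength_nm"]))
                e1.append(float(row["eps_hbo2"]))
                e2.append(float(row["eps_hb"]))
        return cls(np.array(wl), np.array(e1), np.array(e2))

    @classmethod
    def default(cls) -> "ExtinctionTable":
        """The extinction table shipped with the package (compiled standard
        hemoglobin spectra, 650-1000 nm on a 10 nm grid)."""
        ref = resources.files("needleox.data") / "hemoglobin_extinction.csv"
        with resources.as_file(ref) as path:
            return cls.from_csv(path)

    def _check_range(self, wavelength: float) -> None:
        if not (self.wavelengths[0] <= wavelength <= self.wavelengths[-1]):
            raise RangeError(
                f"wavelength {wavelength} nm outside tabulated range "
                f"[{self.wavelengths[0]}, {self.wavelengths[-1]}] nm"
            )

    def lookup(self, wavelength: float) -> tuple[float, float]:
        """Linearly interpolated (eps_hbo2, eps_hb) at ``wavelength`` nm.

        Exact at grid points; raises :class:`RangeError` outside the grid.
        """
        self._check_range(wavelength)
        return (
            float(np.interp(wavelength, self.wavelengths, self.eps_hbo2)),
            float(np.interp(wavelength, self.wavelengths, self.eps_hb)),
        )


@dataclass(frozen=True)
class MeasurementGeometry:
    """Source-detector geometry of the needle-tip probe.

    path_length_cm is the geometric source-detector distance L (cm); dpf maps
    wavelength (nm) to the differential path length factor B(lambda).
    Wavelengths absent from ``dpf`` default to B = 1, the nominal value for
    the short needle-tip geometry.
    """

    path_length_cm: float = 1.0
    dpf: Mapping[float, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.path_length_cm <= 0:
            raise ValueError("path_length_cm must be > 0")
        if any(b <= 0 for b in self.dpf.values()):
            raise ValueError("every DPF value must be > 0")

    def dpf_at(self, wavelength: float) -> float:
        return float(self.dpf.get(wavelength, 1.0))


@dataclass
class HemoglobinState:
    """Relative oxy-/deoxy-hemoglobin concentrations (arbitrary molar scale).

    ``mismatch`` is set by the inversion when a recovered component is
    negative — physically impossible, so it flags model mismatch (e.g. a
    chromophore other than hemoglobin dominating the attenuation) rather
    than being clipped away.
    """

    hbo2: float
    hb: float
    mismatch: bool = False

    @property
    def total(self) -> float:
        return self.hbo2 + self.hb

    @property
    def sto2(self) -> float:
        return tissue_oxygen_saturation(self)


def compute_delta_od(
    incident: Mapping[float, float], received: Mapping[float, float]
) -> dict[float, float]:
    """Optical-density change per wavelength: dOD = -log10(Io / Ii).

    ``incident`` and ``received`` map wavelength (nm) to intensity in the
    same arbitrary linear units (e.g. photodiode volts). dOD > 0 exactly
    when light was attenuated (Io < Ii).
    """
    if set(incident) != set(received):
        raise DomainError(
            f"wavelength sets differ: incident {sorted(incident)} vs "
            f"received {sorted(received)}"
        )
    dod = {}
    for wl in incident:
        ii, io = float(incident[wl]), float(received[wl])
        if ii <= 0:
            raise DomainError(f"incident intensity at {wl} nm is {ii} (must be > 0)")
        if io <= 0:
            raise DomainError(f"received intensity at {wl} nm is {io} (must be > 0)")
        dod[wl] = -np.log10(io / ii)
    return dod


def calibrate_incident(samples: np.ndarray, n: int = 100) -> float:
    """Per-channel incident-intensity reference: mean of the first ``n``
    samples of a baseline recording (the device reports no separate Ii)."""
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise DomainError("cannot calibrate from an empty recording")
    ref = float(samples[: max(1, n)].mean())
    if ref <= 0:
        raise DomainError(f"baseline mean intensity {ref} is not positive")
    return ref


def forward_model(
    state: HemoglobinState,
    geom: MeasurementGeometry,
    table: ExtinctionTable,
    wavelengths=DEFAULT_WAVELENGTHS,
) -> dict[float, float]:
    """Two-chromophore MBLL forward model.

    dOD(lambda) = [eps_HbO2(lambda)*[HbO2] + eps_Hb(lambda)*[Hb]] * L * B(lambda)
    """
    out = {}
    for wl in wavelengths:
        e_hbo2, e_hb = table.lookup(wl)
        out[wl] = (
            (e_hbo2 * state.hbo2 + e_hb * state.hb)
            * geom.path_length_cm
            * geom.dpf_at(wl)
        )
    return out


def _extinction_matrix(
    table: ExtinctionTable, wl1: float, wl2: float
) -> np.ndarray:
    e11, e12 = table.lookup(wl1)  # eps_HbO2(l1), eps_Hb(l1)
    e21, e22 = table.lookup(wl2)
    return np.array([[e11, e12], [e21, e22]])


def invert_hemoglobin(
    dod: Mapping[float, float],
    geom: MeasurementGeometry,
    table: ExtinctionTable,
) -> HemoglobinState:
    """Closed-form dual-wavelength inversion of the MBLL.

    Solves the 2x2 system A [HbO2, Hb]^T = dOD / (L B) by Cramer's rule,
    where A is the extinction matrix over the two wavelengths:

        [HbO2] = (eps_Hb(l2) * d1 - eps_Hb(l1) * d2) / det(A)
        [Hb]   = (eps_HbO2(l1) * d2 - eps_HbO2(l2) * d1) / det(A)

    with d_i = dOD(l_i) / (L * B(l_i)). Raises :class:`ConditioningError`
    when |det(A)| < 1e-9 * ||A||_inf^2, which happens when both wavelengths
    approach the HbO2/Hb isosbestic point (~800 nm) and the system loses
    its oxygenation sensitivity.
    """
    if len(dod) != 2:
        raise DomainError(f"dual-wavelength inversion needs exactly 2 channels, got {len(dod)}")
    wl1, wl2 = sorted(dod)
    a = _extinction_matrix(table, wl1, wl2)
    det = a[0, 0] * a[1, 1] - a[0, 1] * a[1, 0]
    norm_inf = np.abs(a).sum(axis=1).max()
    if abs(det) < DET_RTOL * norm_inf**2:
        raise ConditioningError(
            f"extinction matrix at ({wl1}, {wl2}) nm is near-singular "
            f"(|det| = {abs(det):.3g}); wavelengths too close to the "
            "isosbestic point"
        )
    d1 = float(dod[wl1]) / (geom.path_length_cm * geom.dpf_at(wl1))
    d2 = float(dod[wl2]) / (geom.path_length_cm * geom.dpf_at(wl2))
    hbo2 = (a[1, 1] * d1 - a[0, 1] * d2) / det
    hb = (a[0, 0] * d2 - a[1, 0] * d1) / det
    return HemoglobinState(float(hbo2), float(hb), mismatch=bool(hbo2 < 0 or hb < 0))


def total_hemoglobin(state: HemoglobinState) -> float:
    """[HbT] = [HbO2] + [Hb] (relative scale)."""
    return state.hbo2 + state.hb


def tissue_oxygen_saturation(state: HemoglobinState) -> float:
    """StO2 = 100 * [HbO2] / [HbT], percent. Undefined when [HbT] = 0."""
    hbt = state.hbo2 + state.hb
    if hbt == 0:
        raise DomainError("StO2 undefined: total hemoglobin is zero")
    # divide before scaling so StO2(x, 0) is exactly 100
    return 100.0 * (state.hbo2 / hbt)


def find_isosbestic(
    table: ExtinctionTable, lo: float = 650.0, hi: float = 1000.0
) -> float:
    """Crossing wavelength of the HbO2 and Hb extinction spectra in [lo, hi].

    Root of the linearly interpolated difference eps_HbO2 - eps_Hb, located
    by bisection to better than 0.1 nm. For whole blood this is the
    isosbestic point near 800 nm, where attenuation is insensitive to
    oxygenation — which is why the probe wavelengths straddle it.
    """
    table._check_range(lo)
    table._check_range(hi)

    def diff(wl: float) -> float:
        e_hbo2, e_hb = table.lookup(wl)
        return e_hbo2 - e_hb

    if diff(lo) * diff(hi) > 0:
        raise NotFoundError(
            f"no extinction crossing in [{lo}, {hi}] nm: the difference "
            "has the same sign at both ends"
        )
    return float(brentq(diff, lo, hi, xtol=1e-3))
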