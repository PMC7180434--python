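"""Synthetic dual-wavelength tissue traces for the seven tissue layers met
on the way to the subclavian vessels: skin, fat, muscle, artery, vein,
lung, and pleural cavity.

No public recordings exist for the needle-tip probe, so this module
emulates the measurement: per tissue class a mean optical-density change at
690 and 850 nm, between-trial jitter of that mean, within-trial sample
noise at the 100 Hz sampling rate, and a slow sinusoidal baseline drift.
The default class means (shipped in ``data/tissue_profiles.json``) were
chosen to reproduce every reported ordinal relation among the tissues —
vein above artery at 690 nm but below it at 850 nm (the wavelengths
straddle the ~800 nm isosbestic point), muscle above fat above skin, lung
minimal, pleural cavity maximal, vessels richest in hemoglobin, artery more
oxygen-saturated than vein.

A "trial" is one ~10 s recording in a single tissue layer, reduced to a
single ([HbO2], [Hb]) feature vector by time-averaging the dOD channels
and inverting the MBLL.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Optional

import numpy as np

from .exceptions import DomainError
from .optics import (
    DEFAULT_WAVELENGTHS,
    ExtinctionTable,
    MeasurementGeometry,
    invert_hemoglobin,
)

__all__ = [
    "TISSUE_CLASSES",
    "VESSEL_CLASSES",
    "TissueOpticalProfile",
    "LabeledTrace",
    "default_profiles",
    "generate_trace",
    "trial_features",
    "generate_dataset",
    "Dataset",
]

TISSUE_CLASSES: tuple[str, ...] = (
    "skin",
    "fat",
    "muscle",
    "artery",
    "vein",
    "lung",
    "pleural_cavity",
)
VESSEL_CLASSES: frozenset[str] = frozenset({"artery", "vein"})

SAMPLING_RATE_HZ = 100.0
DEFAULT_DURATION_S = 10.0
DRIFT_FREQ_HZ = 0.2  # slow physiological baseline wander


@dataclass(frozen=True)
class TissueOpticalProfile:
    """Per-class generator parameters.

    mean_dod_690 / mean_dod_850: class-mean dOD (dimensionless, > 0).
    noise_sd, trial_sd, drift_amp: dimensionless fractions of the class
    mean at each wavelength — within-trial sample noise SD, between-trial
    mean jitter SD, and sinusoidal drift amplitude.
    """

    mean_dod_690: float
    mean_dod_850: float
    noise_sd: float = 0.25
    trial_sd: float = 0.1
    drift_amp: float = 0.05

    def __post_init__(self) -> None:
        if self.mean_dod_690 <= 0 or self.mean_dod_850 <= 0:
            raise ValueError("class-mean dOD values must be > 0")
        if min(self.noise_sd, self.trial_sd, self.drift_amp) < 0:
            raise ValueError("noise parameters must be >= 0")

    def scaled(self, factor: float) -> "TissueOpticalProfile":
        """Copy with all noise terms multiplied by ``factor`` (0 gives a
        perfectly deterministic class)."""
        return TissueOpticalProfile(
            self.mean_dod_690,
            self.mean_dod_850,
            self.noise_sd * factor,
            self.trial_sd * factor,
            self.drift_amp * factor,
        )


@dataclass
class LabeledTrace:
    """One trial: dual-wavelength dOD time series with its tissue label."""

    time: np.ndarray
    dod_690: np.ndarray
    dod_850: np.ndarray
    label: str
    duration: float = DEFAULT_DURATION_S

    @property
    def n_samples(self) -> int:
        return self.time.size


def default_profiles() -> dict[str, TissueOpticalProfile]:
    """The shipped per-tissue profile table (see module docstring)."""
    ref = resources.files("needleox.data") / "tissue_profiles.json"
    return load_profiles(ref)


def load_profiles(path) -> dict[str, TissueOpticalProfile]:
    """Read a profile table from a JSON file with a ``classes`` mapping."""
    with open(path) as fh:
        raw = json.load(fh)
    classes = raw["classes"] if "classes" in raw else raw
    profiles = {}
    for name, p in classes.items():
        if name not in TISSUE_CLASSES:
            raise DomainError(f"unknown tissue class {name!r} in profile file")
        profiles[name] = TissueOpticalProfile(
            mean_dod_690=float(p["mean_dod_690"]),
            mean_dod_850=float(p["mean_dod_850"]),
            noise_sd=float(p.get("noise_sd", 0.25)),
            trial_sd=float(p.get("trial_sd", 0.1)),
            drift_amp=float(p.get("drift_amp", 0.05)),
        )
    missing = set(TISSUE_CLASSES) - set(profiles)
    if missing:
        raise DomainError(f"profile file missing classes: {sorted(missing)}")
    return profiles


def generate_trace(
    cls: str,
    profile: TissueOpticalProfile,
    duration: float = DEFAULT_DURATION_S,
    seed: int | np.random.Generator = 0,
) -> LabeledTrace:
    """Simulate one trial in tissue class ``cls``.

    The per-trial mean of each channel is drawn once from
    Normal(mean, trial_sd * mean); samples add white noise
    Normal(0, noise_sd * mean) and a sinusoidal drift of amplitude
    drift_amp * mean at 0.2 Hz with a random phase. Deterministic under a
    fixed seed.
    """
    if cls not in TISSUE_CLASSES:
        raise DomainError(f"unknown tissue class {cls!r}")
    if duration <= 0:
        raise DomainError("duration must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(duration * SAMPLING_RATE_HZ))
    t = np.arange(n) / SAMPLING_RATE_HZ
    channels = {}
    for name, mean in (("dod_690", profile.mean_dod_690), ("dod_850", profile.mean_dod_850)):
        trial_mean = rng.normal(mean, profile.trial_sd * mean)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        drift = profile.drift_amp * mean * np.sin(2.0 * np.pi * DRIFT_FREQ_HZ * t + phase)
        noise = rng.normal(0.0, profile.noise_sd * mean, size=n)
        channels[name] = trial_mean + drift + noise
    return LabeledTrace(
        time=t,
        dod_690=channels["dod_690"],
        dod_850=channels["dod_850"],
        label=cls,
        duration=duration,
    )


def trial_features(
    trace: LabeledTrace,
    geom: Optional[MeasurementGeometry] = None,
    table: Optional[ExtinctionTable] = None,
) -> np.ndarray:
    """Reduce a trial to its ([HbO2], [Hb]) feature pair.

    Time-averages each dOD channel, then applies the closed-form MBLL
    inversion. Order-invariant under sample permutation by construction.
    """
    if trace.n_samples == 0:
        raise DomainError("trace is empty")
    geom = geom or MeasurementGeometry()
    table = table or ExtinctionTable.default()
    dod = {
        DEFAULT_WAVELENGTHS[0]: float(np.mean(trace.dod_690)),
        DEFAULT_WAVELENGTHS[1]: float(np.mean(trace.dod_850)),
    }
    state = invert_hemoglobin(dod, geom, table)
    return np.array([state.hbo2, state.hb])


@dataclass
class Dataset:
    """Per-trial feature vectors and labels for one split."""

    features: np.ndarray  # (n, 2) — [HbO2], [Hb]
    labels: list[str]
    trial_seeds: list[int]

    @property
    def n(self) -> int:
        return self.features.shape[0]

    def class_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in TISSUE_CLASSES}
        for lab in self.labels:
            counts[lab] += 1
        return counts


def _stratified_classes(n: int, rng: np.random.Generator) -> list[str]:
    """n class assignments spread near-uniformly over the 7 tissues
    (counts differ by at most 1), in shuffled order."""
    base, extra = divmod(n, len(TISSUE_CLASSES))
    counts = {c: base for c in TISSUE_CLASSES}
    for c in rng.permutation(np.array(TISSUE_CLASSES))[:extra]:
        counts[str(c)] += 1
    classes = [c for c in TISSUE_CLASSES for _ in range(counts[c])]
    rng.shuffle(classes)
    return classes


def generate_dataset(
    n_train: int = 300,
    n_test: int = 100,
    seed: int = 0,
    profiles: Optional[Mapping[str, TissueOpticalProfile]] = None,
    geom: Optional[MeasurementGeometry] = None,
    table: Optional[ExtinctionTable] = None,
    duration: float = DEFAULT_DURATION_S,
    noise_scale: float = 1.0,
) -> tuple[Dataset, Dataset]:
    """Stratified labeled train/test feature sets.

    Emulates the experimental protocol: n_train trials for training and
    n_test for a blind test, spread near-uniformly across the seven tissue
    classes, each trial an independent 10 s trace reduced to one feature
    vector. The splits are disjoint by construction (independent draws).
    ``noise_scale`` multiplies every profile noise term — 0 yields a
    perfectly separable noiseless dataset.
    """
    if n_train < len(TISSUE_CLASSES) or n_test < len(TISSUE_CLASSES):
        raise DomainError("need at least one trial per tissue class in each split")
    profiles = dict(profiles or default_profiles())
    if noise_scale != 1.0:
        profiles = {c: p.scaled(noise_scale) for c, p in profiles.items()}
    geom = geom or MeasurementGeometry()
    table = table or ExtinctionTable.default()
    master = np.random.default_rng(seed)
    splits = []
    for n in (n_train, n_test):
        classes = _stratified_classes(n, master)
        feats = np.empty((n, 2))
        trial_seeds = [int(s) for s in master.integers(0, 2**31 - 1, size=n)]
        for i, (cls, ts) in enumerate(zip(classes, trial_seeds)):
            trace = generate_trace(cls, profiles[cls], duration=duration, seed=ts)
            feats[i] = trial_features(trace, geom, table)
        splits.append(Dataset(features=feats, labels=classes, trial_seeds=trial_seeds))
    return splits[0], splits[1]


def vessel_labels(labels) -> list[str]:
    """Collapse tissue-class labels to the binary 'vessel'/'other' groups."""
    return ["vessel" if lab in VESSEL_CLASSES else "other" for lab in labels]
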