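"""Synthetic leaf-surface electrophysiological recordings.

Real plant electrome recordings are low-amplitude, low-frequency,
nonstationary voltage series whose statistics shift with the applied
NaCl treatment and with the spatial position of the recording electrode
on the leaf.  This module generates surrogate recordings with exactly
that structure so the full screening + recognition pipeline can be
exercised end to end:

* a per-plant baseline offset (background individual variability),
* a treatment-level baseline shift (waveform centre position),
* band-limited low-frequency drift (the slow-varying main trend),
* a band-limited local-fluctuation process whose envelope grows with
  treatment level (the local fluctuation envelope),
* white sensor noise (independent of treatment).

The treatment terms are scaled by a per-position separability
multiplier so that recording position modulates how well treatment
levels can be told apart — largest, by default, at the basal region of
the top leaf.

The local fluctuation is a narrowband process whose centre frequency
*and* envelope both rise with treatment level.  This is deliberate:
wavelet threshold denoising suppresses broadband sensor noise, and
per-window min-max normalization removes both the baseline shift and
any pure amplitude scale, so the component of the measured waveform
that still carries treatment information after preprocessing is the
*temporal pattern* of the local fluctuations — their timescale relative
to the slow drift.  The default bands (drift below 0.05 Hz, fluctuation
centred at 0.05-0.35 Hz depending on treatment) keep that pattern well
inside the wavelet approximation band, where thresholding leaves it
intact.
"""

from __future__ import annotations

import enum
import itertools
import json
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import h5py
import numpy as np
from scipy import signal as _sig

__all__ = [
    "LeafLevel",
    "Region",
    "PositionLabel",
    "ALL_POSITIONS",
    "CONCENTRATIONS_MM",
    "SCREENING_CONCENTRATIONS_MM",
    "SimulatorConfig",
    "Recording",
    "simulate_recording",
    "simulate_screening_study",
    "simulate_five_gradient_study",
    "write_recording_csv",
    "read_recording_csv",
    "save_recordings_hdf5",
    "load_recordings_hdf5",
]


class LeafLevel(str, enum.Enum):
    """Vertical canopy position of the recorded leaf."""

    TOP = "top"
    MIDDLE = "middle"
    BOTTOM = "bottom"


class Region(str, enum.Enum):
    """Longitudinal region along the leaf axis."""

    BASAL = "basal"
    MIDDLE = "middle"
    APICAL = "apical"


@dataclass(frozen=True, order=True)
class PositionLabel:
    """One of the nine candidate recording locations (leaf level x region)."""

    leaf_level: LeafLevel
    region: Region

    def key(self) -> str:
        return f"{self.leaf_level.value}-{self.region.value}"

    @classmethod
    def from_key(cls, key: str) -> "PositionLabel":
        level, region = key.split("-")
        return cls(LeafLevel(level), Region(region))

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.key()


#: All nine candidate recording locations, in a stable order.
ALL_POSITIONS: tuple[PositionLabel, ...] = tuple(
    PositionLabel(lv, rg) for lv in LeafLevel for rg in Region
)

#: NaCl treatment levels (mM) used across the study designs.
CONCENTRATIONS_MM: tuple[int, ...] = (0, 100, 200, 300, 400)
#: The two levels used for the binary position-screening task.
SCREENING_CONCENTRATIONS_MM: tuple[int, ...] = (0, 100)

# Default separability gradient: basal > middle > apical along the leaf,
# top > middle > bottom across the canopy; multiplicative so top-basal is
# the unique maximum.  The steps are large enough that the weaker
# positions do not saturate the binary screening task.
_LEVEL_FACTOR = {LeafLevel.TOP: 1.0, LeafLevel.MIDDLE: 0.45, LeafLevel.BOTTOM: 0.25}
_REGION_FACTOR = {Region.BASAL: 1.0, Region.MIDDLE: 0.35, Region.APICAL: 0.2}


def default_position_effect() -> dict[PositionLabel, float]:
    """Per-position separability multipliers in [0, 1], 1.0 at top-basal."""
    return {
        p: _LEVEL_FACTOR[p.leaf_level] * _REGION_FACTOR[p.region]
        for p in ALL_POSITIONS
    }


@dataclass
class SimulatorConfig:
    """Parameters of the synthetic recording generator.

    Amplitudes are in millivolts.  ``baseline_mV_per_mM`` shifts the
    signal centre per mM of NaCl.  The local-fluctuation process is a
    narrowband noise centred at ``fluctuation_center_hz`` whose RMS is
    ``noise_sd_mV`` scaled by ``1 + envelope_gain_per_mM * mM`` and
    whose centre frequency is scaled by
    ``1 + fluctuation_freq_gain_per_mM * mM`` (faster, stronger local
    fluctuations under stronger treatment).  Both treatment effects are
    multiplied by the per-position separability factor, so positions
    with a small factor yield nearly indistinguishable classes.
    ``drift_amplitude_mV`` is the RMS of the slow
    (< ``drift_cutoff_hz``) drift and ``sensor_noise_sd_mV`` the SD of
    treatment-independent white sensor noise.
    """

    sampling_rate_hz: float = 30.0
    duration_s: float = 7200.0
    baseline_mV_per_mM: float = 0.01
    envelope_gain_per_mM: float = 0.005
    fluctuation_freq_gain_per_mM: float = 0.015
    drift_amplitude_mV: float = 0.3
    drift_cutoff_hz: float = 0.05
    noise_sd_mV: float = 0.3
    fluctuation_center_hz: float = 0.05
    fluctuation_rel_bandwidth: float = 0.4
    sensor_noise_sd_mV: float = 0.05
    position_effect: dict[PositionLabel, float] = field(
        default_factory=default_position_effect
    )
    plant_effect_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate_hz <= 0 or self.duration_s <= 0:
            raise ValueError("sampling rate and duration must be positive")
        n = self.sampling_rate_hz * self.duration_s
        if abs(n - round(n)) > 1e-9 or round(n) <= 0:
            raise ValueError(
                f"duration_s * sampling_rate_hz = {n} is not a positive integer"
            )
        if not 0 < self.drift_cutoff_hz < self.sampling_rate_hz / 2:
            raise ValueError("drift_cutoff_hz must lie below the Nyquist frequency")
        if not 0 < self.fluctuation_rel_bandwidth < 1:
            raise ValueError("fluctuation_rel_bandwidth must be in (0, 1)")
        fc_max = self.fluctuation_center_hz * (
            1.0 + self.fluctuation_freq_gain_per_mM * max(CONCENTRATIONS_MM)
        )
        if fc_max * (1.0 + self.fluctuation_rel_bandwidth) >= self.sampling_rate_hz / 2:
            raise ValueError(
                "fluctuation band exceeds the Nyquist frequency at the "
                "highest treatment level"
            )
        for name in ("envelope_gain_per_mM", "fluctuation_freq_gain_per_mM",
                     "drift_amplitude_mV", "noise_sd_mV", "fluctuation_center_hz",
                     "sensor_noise_sd_mV", "plant_effect_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        for pos, mult in self.position_effect.items():
            if not 0.0 <= mult <= 1.0:
                raise ValueError(f"position multiplier for {pos} outside [0, 1]")

    @property
    def n_samples(self) -> int:
        return int(round(self.sampling_rate_hz * self.duration_s))


@dataclass
class Recording:
    """One continuous labelled voltage series."""

    values: np.ndarray  # mV
    sampling_rate_hz: float
    plant_id: str
    position: PositionLabel
    concentration_mM: int
    seed_used: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("recording contains non-finite values")

    @property
    def duration_s(self) -> float:
        return len(self.values) / self.sampling_rate_hz


def _stream(seed: int, *tokens: object) -> np.random.Generator:
    """Deterministic child generator keyed by (seed, tokens)."""
    keys = [zlib.crc32(str(t).encode("utf8")) for t in tokens]
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=keys))


def _plant_offset(config: SimulatorConfig, plant_id: str, seed: int) -> float:
    rng = _stream(seed, "plant", plant_id)
    return float(rng.normal(0.0, config.plant_effect_sd))


def _shaped_noise(
    rng: np.random.Generator,
    n: int,
    rms: float,
    sos: np.ndarray,
) -> np.ndarray:
    """Filtered white noise rescaled to a target RMS."""
    if rms == 0.0:
        return np.zeros(n)
    shaped = _sig.sosfiltfilt(sos, rng.standard_normal(n))
    actual = float(np.sqrt(np.mean(shaped**2)))
    if actual == 0.0:  # pragma: no cover - degenerate filter output
        return np.zeros(n)
    return shaped * (rms / actual)


def _drift_sos(config: SimulatorConfig) -> np.ndarray:
    # 4th-order Butterworth low-pass, zero phase, below the drift cutoff.
    return _sig.butter(
        4, config.drift_cutoff_hz, btype="low", fs=config.sampling_rate_hz,
        output="sos",
    )


def _fluctuation_sos(config: SimulatorConfig, center_hz: float) -> np.ndarray:
    bw = config.fluctuation_rel_bandwidth
    band = (center_hz * (1.0 - bw), center_hz * (1.0 + bw))
    return _sig.butter(
        4, band, btype="bandpass", fs=config.sampling_rate_hz, output="sos",
    )


def simulate_recording(
    config: SimulatorConfig,
    plant_id: str,
    position: PositionLabel,
    concentration_mM: int,
    seed: int | None = None,
) -> Recording:
    """Simulate one continuous recording.

    The per-plant baseline offset depends only on ``(seed, plant_id)``,
    so all recordings of the same plant within one study share it.
    Identical arguments yield byte-identical output.
    """
    if concentration_mM not in CONCENTRATIONS_MM:
        raise ValueError(
            f"concentration_mM must be one of {CONCENTRATIONS_MM}, "
            f"got {concentration_mM!r}"
        )
    if position not in config.position_effect:
        raise ValueError(f"no position multiplier configured for {position}")
    seed = config.seed if seed is None else int(seed)

    n = config.n_samples
    mult = config.position_effect[position]
    rng = _stream(seed, "rec", plant_id, position.key(), concentration_mM)

    baseline = config.baseline_mV_per_mM * concentration_mM * mult
    envelope = 1.0 + config.envelope_gain_per_mM * concentration_mM * mult
    center = config.fluctuation_center_hz * (
        1.0 + config.fluctuation_freq_gain_per_mM * concentration_mM * mult
    )
    values = np.full(n, _plant_offset(config, plant_id, seed) + baseline)
    values += _shaped_noise(rng, n, config.drift_amplitude_mV, _drift_sos(config))
    values += _shaped_noise(
        rng, n, config.noise_sd_mV * envelope, _fluctuation_sos(config, center)
    )
    if config.sensor_noise_sd_mV > 0:
        values += rng.normal(0.0, config.sensor_noise_sd_mV, size=n)
    return Recording(
        values=values,
        sampling_rate_hz=config.sampling_rate_hz,
        plant_id=str(plant_id),
        position=position,
        concentration_mM=int(concentration_mM),
        seed_used=seed,
    )


DEFAULT_PLANTS: tuple[str, ...] = ("plant-1", "plant-2", "plant-3")


def simulate_screening_study(
    config: SimulatorConfig,
    seed: int | None = None,
    plants: Sequence[str] = DEFAULT_PLANTS,
) -> list[Recording]:
    """Full position-screening design: 3 plants x 9 positions x {0, 100} mM.

    Returns 54 recordings with deterministic per-recording seeding derived
    from the study seed.
    """
    seed = config.seed if seed is None else int(seed)
    return [
        simulate_recording(config, plant, pos, conc, seed=seed)
        for plant, pos, conc in itertools.product(
            plants, ALL_POSITIONS, SCREENING_CONCENTRATIONS_MM
        )
    ]


def simulate_five_gradient_study(
    config: SimulatorConfig,
    optimal_position: PositionLabel,
    seed: int | None = None,
    plants: Sequence[str] = DEFAULT_PLANTS,
) -> list[Recording]:
    """Five-gradient design at one position: 3 plants x 5 concentrations."""
    seed = config.seed if seed is None else int(seed)
    return [
        simulate_recording(config, plant, optimal_position, conc, seed=seed)
        for plant, conc in itertools.product(plants, CONCENTRATIONS_MM)
    ]


# ---------------------------------------------------------------------------
# Recording I/O: per-recording CSV + JSON sidecar, batch HDF5 container.
# ---------------------------------------------------------------------------

def _metadata(rec: Recording) -> dict:
    return {
        "sampling_rate_hz": rec.sampling_rate_hz,
        "plant_id": rec.plant_id,
        "position": rec.position.key(),
        "concentration_mM": rec.concentration_mM,
        "seed_used": rec.seed_used,
    }


def write_recording_csv(rec: Recording, path: str | Path) -> None:
    """Write one recording as ``time_s,value_mV`` CSV plus a JSON sidecar."""
    path = Path(path)
    t = np.arange(len(rec.values)) / rec.sampling_rate_hz
    arr = np.column_stack([t, rec.values])
    np.savetxt(path, arr, delimiter=",", header="time_s,value_mV", comments="")
    path.with_suffix(".json").write_text(json.dumps(_metadata(rec), indent=2))


def read_recording_csv(path: str | Path) -> Recording:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    arr = np.loadtxt(path, delimiter=",", skiprows=1)
    return Recording(
        values=arr[:, 1],
        sampling_rate_hz=float(meta["sampling_rate_hz"]),
        plant_id=meta["plant_id"],
        position=PositionLabel.from_key(meta["position"]),
        concentration_mM=int(meta["concentration_mM"]),
        seed_used=int(meta["seed_used"]),
    )


def save_recordings_hdf5(recordings: Iterable[Recording], path: str | Path) -> None:
    """Batch container: one dataset per recording, metadata as attributes."""
    with h5py.File(path, "w") as f:
        for i, rec in enumerate(recordings):
            ds = f.create_dataset(f"recording_{i:04d}", data=rec.values)
            for k, v in _metadata(rec).items():
                ds.attrs[k] = v


def load_recordings_hdf5(path: str | Path) -> list[Recording]:
    out: list[Recording] = []
    with h5py.File(path, "r") as f:
        for name in sorted(f.keys()):
            ds = f[name]
            out.append(
                Recording(
                    values=ds[()],
                    sampling_rate_hz=float(ds.attrs["sampling_rate_hz"]),
                    plant_id=str(ds.attrs["plant_id"]),
                    position=PositionLabel.from_key(str(ds.attrs["position"])),
                    concentration_mM=int(ds.attrs["concentration_mM"]),
                    seed_used=int(ds.attrs["seed_used"]),
                )
            )
    return out


def reduced_config(duration_s: float = 300.0, **overrides) -> SimulatorConfig:
    """A short-duration configuration for quick studies and examples.

    Identical signal model to the defaults; only the recording length
    (and hence the number of 30 s windows per recording) is reduced.
    """
    return replace(SimulatorConfig(), duration_s=duration_s, **overrides)
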