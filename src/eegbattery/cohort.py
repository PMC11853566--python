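"""Synthetic cohort generation: demographics, epoched EEG, and feature tables.

Ground-truth effects (age slopes, sex offsets, diagnosis offsets, PAC depth,
inter-channel coupling) are configurable so downstream recovery can be tested
without any real data.  Two simulation granularities are provided:

* :func:`generate_recording` / :func:`generate_cohort` build epoched
  multichannel EEG time series (1/f background + band oscillations + noise),
  to be run through the signal-feature extraction stack.
* :func:`simulate_feature_table` injects effects directly at the level of the
  726-variable feature battery, which makes cohort-scale statistical
  experiments tractable on one CPU.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from eegbattery.layout import ChannelLayout, default_layout
from eegbattery.registry import BANDS, VariableRegistry

DEMOGRAPHICS_COLUMNS = ["participant_id", "age_months", "sex", "iq", "diagnosis", "dataset"]
DIAGNOSES = ("AD", "ASD", "CON")

#: Default age strata (months), mirroring a tertile structure spanning 3-248.
DEFAULT_AGE_STRATA = ((3.0, 96.0), (98.0, 126.0), (128.0, 248.0))


@dataclass
class CohortConfig:
    """Cohort composition: participants per diagnosis within each age stratum."""

    n_per_stratum: dict[str, tuple[int, ...]] = field(
        default_factory=lambda: {"AD": (10, 10, 10), "ASD": (10, 10, 10), "CON": (10, 10, 10)}
    )
    age_strata: tuple[tuple[float, float], ...] = DEFAULT_AGE_STRATA
    female_fraction: float = 0.4
    iq_mean: float = 100.0
    iq_sd: float = 15.0
    dataset: str = "synthetic"

    def total(self) -> int:
        return int(sum(sum(v) for v in self.n_per_stratum.values()))

    def validate(self) -> None:
        if self.total() <= 0:
            raise ValueError("total cohort size must be positive")
        if not 0.0 <= self.female_fraction <= 1.0:
            raise ValueError("female_fraction must lie in [0, 1]")
        for diag, counts in self.n_per_stratum.items():
            if diag not in DIAGNOSES:
                raise ValueError(f"unknown diagnosis {diag!r}")
            if len(counts) != len(self.age_strata):
                raise ValueError("counts per diagnosis must match number of age strata")
            if any(n < 0 for n in counts):
                raise ValueError("stratum sizes must be >= 0")


@dataclass
class EffectSpec:
    """Ground-truth signal composition for EEG time-series generation.

    Amplitudes are in µV; slopes/offsets are additive changes to band
    amplitude (µV) per standardized covariate unit.  A default-constructed
    spec is the null model: no covariate influences the signal.
    """

    osc_amplitude: dict[str, float] = field(default_factory=lambda: {b: 0.0 for b in BANDS})
    aperiodic_exponent_mean: float = 1.5
    aperiodic_exponent_sd: float = 0.2
    aperiodic_amplitude: float = 1.0
    age_slope: dict[str, float] = field(default_factory=dict)
    sex_offset: dict[str, float] = field(default_factory=dict)
    diagnosis_offset: dict[str, dict[str, float]] = field(default_factory=dict)
    pac_depth: dict[tuple[str, str], float] = field(default_factory=dict)
    coupling: dict[str, float] = field(default_factory=dict)
    noise_sd: float = 0.0

    def validate(self) -> None:
        for band, amp in self.osc_amplitude.items():
            if band not in BANDS:
                raise ValueError(f"unknown band {band!r}")
            if amp < 0:
                raise ValueError("oscillation amplitudes must be non-negative")
        for (lo, hi), depth in self.pac_depth.items():
            if lo not in BANDS or hi not in BANDS:
                raise ValueError(f"unknown PAC band pair ({lo!r}, {hi!r})")
            if not 0 <= depth <= 1:
                raise ValueError("PAC depth must lie in [0, 1]")
        for band, c in self.coupling.items():
            if not 0 <= c <= 1:
                raise ValueError("coupling strength must lie in [0, 1]")

    def band_amplitude(self, band: str, age_z: float, sex: str, diagnosis: str) -> float:
        """Oscillation amplitude for one participant, clipped at zero."""
        amp = self.osc_amplitude.get(band, 0.0)
        amp += self.age_slope.get(band, 0.0) * age_z
        if sex == "F":
            amp += self.sex_offset.get(band, 0.0)
        amp += self.diagnosis_offset.get(band, {}).get(diagnosis, 0.0)
        return max(amp, 0.0)


@dataclass
class EpochedEEG:
    """One participant's cleaned epoched recording."""

    participant_id: str
    sampling_rate: float
    data: np.ndarray  # (epochs, channels, samples), µV
    layout: ChannelLayout

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 3:
            raise ValueError("data must be (epochs, channels, samples)")
        if data.shape[0] < 1:
            raise ValueError("at least one epoch required")
        if data.shape[1] != self.layout.n_channels:
            raise ValueError("channel count must match layout")
        if not np.all(np.isfinite(data)):
            raise ValueError("data must be finite")
        self.data = data

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]


def generate_demographics(config: CohortConfig, seed: int) -> pd.DataFrame:
    """Draw a demographics table with the requested per-stratum counts.

    Deterministic under a fixed seed.  Sex is assigned by rounding the
    requested female fraction within each (diagnosis, stratum) cell so cell
    compositions are stable across seeds.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    rows = []
    idx = 0
    for diag in sorted(config.n_per_stratum):
        for s, (lo, hi) in enumerate(config.age_strata):
            n = config.n_per_stratum[diag][s]
            if n == 0:
                continue
            ages = rng.uniform(lo, hi, size=n)
            iqs = rng.normal(config.iq_mean, config.iq_sd, size=n)
            n_female = int(round(config.female_fraction * n))
            sexes = np.array(["F"] * n_female + ["M"] * (n - n_female))
            rng.shuffle(sexes)
            for a, q, sx in zip(ages, iqs, sexes):
                rows.append(
                    {
                        "participant_id": f"sub-{idx:04d}",
                        "age_months": float(a),
                        "sex": str(sx),
                        "iq": float(q),
                        "diagnosis": diag,
                        "dataset": config.dataset,
                    }
                )
                idx += 1
    return pd.DataFrame(rows, columns=DEMOGRAPHICS_COLUMNS)


def _aperiodic_background(rng: np.random.Generator, n_samples: int, fs: float, exponent: float, amplitude: float) -> np.ndarray:
    """1/f^x noise via spectral shaping of white noise; zero-mean, unit-free scale."""
    white = rng.standard_normal(n_samples)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    shape = np.ones_like(freqs)
    nonzero = freqs > 0
    shape[nonzero] = freqs[nonzero] ** (-exponent / 2.0)
    shape[0] = 0.0
    shaped = np.fft.irfft(spec * shape, n=n_samples)
    sd = shaped.std()
    if sd > 0:
        shaped = shaped / sd
    return amplitude * shaped


def generate_recording(
    record: pd.Series | dict,
    effects: EffectSpec,
    layout: ChannelLayout | None = None,
    *,
    n_epochs: int = 60,
    sampling_rate: float = 250.0,
    epoch_length: int = 500,
    seed: int = 0,
    age_z: float | None = None,
) -> EpochedEEG:
    """Synthesize one participant's epoched EEG from an effect specification.

    The signal per channel is a sum of a 1/f^x background, band-centred
    oscillations whose amplitudes depend on the participant's covariates,
    optional phase-amplitude modulation and cross-channel shared sources,
    and white noise.

    Parameters
    ----------
    record : mapping
        Demographics row with age_months, sex, diagnosis fields.
    age_z : float, optional
        Standardized age used to evaluate age slopes; defaults to 0 (only
        meaningful when a cohort-level standardization is available).
    """
    effects.validate()
    if layout is None:
        layout = default_layout()
    if n_epochs < 1:
        raise ValueError("n_epochs must be >= 1")
    if sampling_rate < 2 * 80.0:
        raise ValueError("sampling_rate must be at least 160 Hz (2x the 80 Hz analysis limit)")
    lowest = min(lo for lo, _ in BANDS.values())
    if epoch_length < 2 * sampling_rate / lowest:
        raise ValueError(f"epoch_length must cover at least 2 cycles of {lowest} Hz")

    rng = np.random.default_rng(seed)
    rec = dict(record)
    z = 0.0 if age_z is None else float(age_z)
    n_ch = layout.n_channels
    t = np.arange(epoch_length) / sampling_rate
    exponent = max(float(rng.normal(effects.aperiodic_exponent_mean, effects.aperiodic_exponent_sd)), 0.5)

    amp = {
        band: effects.band_amplitude(band, z, rec["sex"], rec["diagnosis"])
        for band in BANDS
    }
    centres = {band: 0.5 * (lo + hi) for band, (lo, hi) in BANDS.items()}
    # Amplitude bands modulated by some phase band, keyed by amplitude band.
    modulators = {hi: (lo, d) for (lo, hi), d in effects.pac_depth.items() if d > 0}

    data = np.empty((n_epochs, n_ch, epoch_length))
    for e in range(n_epochs):
        shared_phase = {band: rng.uniform(0, 2 * np.pi) for band in BANDS}
        for c in range(n_ch):
            x = np.zeros(epoch_length)
            if effects.aperiodic_amplitude > 0:
                x += _aperiodic_background(
                    rng, epoch_length, sampling_rate, exponent, effects.aperiodic_amplitude
                )
            phases = {band: rng.uniform(0, 2 * np.pi) for band in BANDS}
            angle = {band: 2 * np.pi * centres[band] * t + phases[band] for band in BANDS}
            for band in BANDS:
                if amp[band] <= 0:
                    continue
                mix = effects.coupling.get(band, 0.0)
                osc = (1 - mix) * np.cos(angle[band]) + mix * np.cos(
                    2 * np.pi * centres[band] * t + shared_phase[band]
                )
                if band in modulators:
                    low_band, depth = modulators[band]
                    osc = osc * (1 + depth * np.cos(angle[low_band])) / (1 + depth)
                x += amp[band] * osc
            if effects.noise_sd > 0:
                x += rng.normal(0, effects.noise_sd, size=epoch_length)
            data[e, c] = x

    return EpochedEEG(
        participant_id=str(rec["participant_id"]),
        sampling_rate=sampling_rate,
        data=data,
        layout=layout,
    )


def generate_cohort(
    config: CohortConfig,
    effects: EffectSpec,
    seed: int,
    layout: ChannelLayout | None = None,
    **recording_kwargs,
) -> tuple[pd.DataFrame, dict[str, EpochedEEG]]:
    """Demographics table plus one recording per participant.

    Per-participant seeds are spawned deterministically from the master seed,
    so recordings do not depend on generation order.
    """
    if layout is None:
        layout = default_layout()
    demographics = generate_demographics(config, seed)
    ages = demographics["age_months"].to_numpy()
    sd = ages.std(ddof=0)
    age_z = (ages - ages.mean()) / sd if sd > 0 else np.zeros_like(ages)
    seeds = np.random.SeedSequence(seed).spawn(len(demographics))
    recordings = {}
    for i, (_, row) in enumerate(demographics.iterrows()):
        sub_seed = int(seeds[i].generate_state(1)[0])
        recordings[row["participant_id"]] = generate_recording(
            row, effects, layout, seed=sub_seed, age_z=float(age_z[i]), **recording_kwargs
        )
    return demographics, recordings


@dataclass
class FeatureEffect:
    """One injected effect at feature level; None fields match anything.

    ``family`` matches by prefix ("power" matches all three power forms),
    ``qualifier`` and ``grouping`` match exactly.  Betas are on the scale of
    the unit-variance feature noise (standardized effect sizes).
    """

    family: str | None = None
    qualifier: str | None = None
    grouping: str | None = None
    age_beta: float = 0.0
    sex_beta: float = 0.0
    diagnosis_betas: dict[str, float] = field(default_factory=dict)
    iq_beta: float = 0.0

    def matches(self, key) -> bool:
        if self.family is not None and not key.family.startswith(self.family):
            return False
        if self.qualifier is not None and key.qualifier != self.qualifier:
            return False
        if self.grouping is not None and key.grouping != self.grouping:
            return False
        return True


@dataclass
class FeatureEffects:
    """Collection of feature-level injected effects; empty = global null."""

    effects: list[FeatureEffect] = field(default_factory=list)
    noise_sd: float = 1.0


def simulate_feature_table(
    demographics: pd.DataFrame,
    registry: VariableRegistry,
    effects: FeatureEffects | None = None,
    seed: int = 0,
    age_standardization: str = "tertile",
) -> pd.DataFrame:
    """Draw a participants x variables feature table with injected effects.

    Each variable is unit-variance Gaussian noise plus the summed
    standardized contributions of every matching :class:`FeatureEffect`
    (sex coded F=+0.5/M=-0.5, IQ z-scored).  Age is z-scored within
    age-rank tertiles by default so an injected standardized slope remains
    a within-age-group effect of that magnitude, matching the tertile-wise
    analysis downstream; pass ``age_standardization="cohort"`` for a single
    cohort-wide z-score.  Deterministic under seed; columns follow registry
    order.
    """
    if effects is None:
        effects = FeatureEffects()
    rng = np.random.default_rng(seed)
    n = len(demographics)
    ages = demographics["age_months"].to_numpy(dtype=float)
    iqs = demographics["iq"].to_numpy(dtype=float)
    if age_standardization == "tertile":
        ranks = np.argsort(np.argsort(ages, kind="stable"), kind="stable")
        tert = np.minimum(ranks * 3 // max(n, 1), 2)
        age_z = np.zeros(n)
        for t in range(3):
            mask = tert == t
            sd = ages[mask].std(ddof=0)
            if sd > 0:
                age_z[mask] = (ages[mask] - ages[mask].mean()) / sd
    elif age_standardization == "cohort":
        age_z = (ages - ages.mean()) / ages.std(ddof=0) if ages.std(ddof=0) > 0 else np.zeros(n)
    else:
        raise ValueError("age_standardization must be 'tertile' or 'cohort'")
    iq_z = (iqs - iqs.mean()) / iqs.std(ddof=0) if iqs.std(ddof=0) > 0 else np.zeros(n)
    sex_c = np.where(demographics["sex"].to_numpy() == "F", 0.5, -0.5)
    diag = demographics["diagnosis"].to_numpy()

    values = rng.normal(0.0, effects.noise_sd, size=(n, len(registry)))
    for j, key in enumerate(registry.keys):
        for eff in effects.effects:
            if not eff.matches(key):
                continue
            col = values[:, j]
            col += eff.age_beta * age_z + eff.sex_beta * sex_c + eff.iq_beta * iq_z
            for group, beta in eff.diagnosis_betas.items():
                col[diag == group] += beta
    table = pd.DataFrame(values, columns=[k.name for k in registry.keys])
    table.insert(0, "participant_id", demographics["participant_id"].to_numpy())
    return table
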