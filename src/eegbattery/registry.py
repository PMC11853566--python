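"""The canonical 726-variable dependent-measure registry and aggregation.

Variables are (metric family x channel grouping x band/qualifier) cells:
324 power + 36 aperiodic slope + 36 peak-alpha + 216 PAC + 72 MSE + 42 ISPC.
Channel groupings are 13 regional means plus 5 asymmetry difference scores
(18 total); ISPC uses its own 7 channel-pair contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from eegbattery.layout import ASYMMETRY_CONTRASTS, ChannelLayout, ispc_contrasts, regional_groups

#: Canonical frequency bands (Hz), contiguous over 2-80.
BANDS: dict[str, tuple[float, float]] = {
    "delta": (2.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 14.0),
    "beta": (14.0, 30.0),
    "gamma_low": (30.0, 50.0),
    "gamma_high": (50.0, 80.0),
}

#: Phase-band x amplitude-band pairs for PAC (12, giving 216 PAC variables).
PAC_PAIRS: tuple[tuple[str, str], ...] = tuple(
    (p, a) for p in ("delta", "theta", "alpha", "beta") for a in ("beta", "gamma_low", "gamma_high")
)

#: Multiscale-entropy scale bins: 20 scales averaged into 4 bins.
MSE_BINS: tuple[tuple[int, int], ...] = ((1, 5), (6, 10), (11, 15), (16, 20))

FAMILIES = (
    "power-absolute",
    "power-relative",
    "power-log",
    "slope-exponent",
    "slope-offset",
    "paf-frequency",
    "paf-amplitude",
    "pac",
    "mse",
    "ispc",
)


@dataclass(frozen=True)
class VariableKey:
    """One dependent variable: family + channel grouping + qualifier."""

    family: str
    grouping: str
    qualifier: str | None = None

    @property
    def name(self) -> str:
        if self.qualifier is None:
            return f"{self.family}.{self.grouping}"
        return f"{self.family}.{self.grouping}.{self.qualifier}"


@dataclass
class VariableRegistry:
    """Ordered collection of variable keys plus the grouping definitions."""

    keys: list[VariableKey]
    regional: dict[str, list[str]]
    asymmetry: dict[str, tuple[str, str]]
    ispc_pairs: dict[str, list[tuple[str, str]]]
    bands: dict[str, tuple[float, float]] = field(default_factory=lambda: dict(BANDS))
    pac_pairs: tuple[tuple[str, str], ...] = PAC_PAIRS
    mse_bins: tuple[tuple[int, int], ...] = MSE_BINS

    def __len__(self) -> int:
        return len(self.keys)

    @property
    def names(self) -> list[str]:
        return [k.name for k in self.keys]

    @property
    def groupings(self) -> list[str]:
        """The 18 channel groupings (13 regional + 5 asymmetry)."""
        return list(self.regional) + list(self.asymmetry)

    def family_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for k in self.keys:
            counts[k.family] = counts.get(k.family, 0) + 1
        return counts

    def subset(self, n: int, seed: int | None = None) -> "VariableRegistry":
        """A registry restricted to n variables (evenly spread, or seeded random)."""
        if n >= len(self.keys):
            return self
        if seed is None:
            idx = np.linspace(0, len(self.keys) - 1, n).round().astype(int)
        else:
            idx = np.sort(np.random.default_rng(seed).choice(len(self.keys), n, replace=False))
        return VariableRegistry(
            keys=[self.keys[i] for i in idx],
            regional=self.regional,
            asymmetry=self.asymmetry,
            ispc_pairs=self.ispc_pairs,
            bands=self.bands,
            pac_pairs=self.pac_pairs,
            mse_bins=self.mse_bins,
        )

    def to_manifest(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"name": k.name, "family": k.family, "grouping": k.grouping, "qualifier": k.qualifier or ""}
                for k in self.keys
            ]
        )


def build_registry(layout: ChannelLayout) -> VariableRegistry:
    """Enumerate the default dependent-variable registry for a layout.

    Deterministic ordering: families in canonical order, groupings in fixed
    order (13 regional, then 5 asymmetry), qualifiers in band/pair/bin order.
    Raises if any grouping resolves to zero channels on this layout.
    """
    regional = regional_groups(layout)
    asymmetry = dict(ASYMMETRY_CONTRASTS)
    pairs = ispc_contrasts(layout)
    grouping_names = list(regional) + list(asymmetry)

    keys: list[VariableKey] = []
    for family in ("power-absolute", "power-relative", "power-log"):
        for grouping in grouping_names:
            for band in BANDS:
                keys.append(VariableKey(family, grouping, band))
    for family in ("slope-exponent", "slope-offset"):
        for grouping in grouping_names:
            keys.append(VariableKey(family, grouping))
    for family in ("paf-frequency", "paf-amplitude"):
        for grouping in grouping_names:
            keys.append(VariableKey(family, grouping))
    for grouping in grouping_names:
        for phase, amp in PAC_PAIRS:
            keys.append(VariableKey("pac", grouping, f"{phase}->{amp}"))
    for grouping in grouping_names:
        for lo, hi in MSE_BINS:
            keys.append(VariableKey("mse", grouping, f"scales-{lo:02d}-{hi:02d}"))
    for contrast in pairs:
        for band in BANDS:
            keys.append(VariableKey("ispc", contrast, band))

    return VariableRegistry(keys=keys, regional=regional, asymmetry=asymmetry, ispc_pairs=pairs)


@dataclass
class ParticipantMetrics:
    """Per-channel metric values for one participant, pre-aggregation.

    Power arrays are (n_channels, n_freqs) on ``grid``; ``pac`` maps a
    "phase->amp" pair label to per-channel MI; ``ispc`` maps a band name to
    a {(ch_a, ch_b): value} dict; NaN marks undefined values.
    """

    channel_names: list[str]
    grid: np.ndarray
    power_absolute: np.ndarray
    power_relative: np.ndarray
    power_log: np.ndarray
    exponent: np.ndarray
    offset: np.ndarray
    paf_frequency: np.ndarray
    paf_amplitude: np.ndarray
    pac: dict[str, np.ndarray]
    mse: np.ndarray  # (n_channels, n_scales)
    ispc: dict[str, dict[tuple[str, str], float]]


def _band_mask(grid: np.ndarray, band: str, bands: dict[str, tuple[float, float]]) -> np.ndarray:
    lo, hi = bands[band]
    top = max(b[1] for b in bands.values())
    if hi >= top:
        return (grid >= lo) & (grid <= hi)
    return (grid >= lo) & (grid < hi)


def aggregate(metrics: ParticipantMetrics, registry: VariableRegistry) -> pd.Series:
    """Collapse per-channel metrics into one registry-ordered feature row.

    Regional values are means over member channels (and over band
    frequencies / scale bins); asymmetry values are differences of the two
    constituent regional means; relative power uses the band *sum* over
    grid frequencies so the six bands partition each channel's total.
    Missing inputs propagate as NaN.
    """
    ch_index = {name: i for i, name in enumerate(metrics.channel_names)}

    def member_idx(grouping: str) -> np.ndarray:
        return np.array([ch_index[c] for c in registry.regional[grouping]], dtype=int)

    def regional_value(grouping: str, per_channel: np.ndarray) -> float:
        return float(np.mean(per_channel[member_idx(grouping)]))

    def grouping_value(grouping: str, per_channel: np.ndarray) -> float:
        if grouping in registry.regional:
            return regional_value(grouping, per_channel)
        a, b = registry.asymmetry[grouping]
        return regional_value(a, per_channel) - regional_value(b, per_channel)

    band_channel: dict[tuple[str, str], np.ndarray] = {}
    for family, arr in (
        ("power-absolute", metrics.power_absolute),
        ("power-relative", metrics.power_relative),
        ("power-log", metrics.power_log),
    ):
        for band in registry.bands:
            mask = _band_mask(metrics.grid, band, registry.bands)
            if family == "power-relative":
                band_channel[(family, band)] = arr[:, mask].sum(axis=1)
            else:
                band_channel[(family, band)] = arr[:, mask].mean(axis=1)

    mse_bin: dict[str, np.ndarray] = {}
    for lo, hi in registry.mse_bins:
        label = f"scales-{lo:02d}-{hi:02d}"
        mse_bin[label] = metrics.mse[:, lo - 1 : hi].mean(axis=1)

    values: dict[str, float] = {}
    for key in registry.keys:
        if key.family.startswith("power-"):
            v = grouping_value(key.grouping, band_channel[(key.family, key.qualifier)])
        elif key.family == "slope-exponent":
            v = grouping_value(key.grouping, metrics.exponent)
        elif key.family == "slope-offset":
            v = grouping_value(key.grouping, metrics.offset)
        elif key.family == "paf-frequency":
            v = grouping_value(key.grouping, metrics.paf_frequency)
        elif key.family == "paf-amplitude":
            v = grouping_value(key.grouping, metrics.paf_amplitude)
        elif key.family == "pac":
            v = grouping_value(key.grouping, metrics.pac[key.qualifier])
        elif key.family == "mse":
            v = grouping_value(key.grouping, mse_bin[key.qualifier])
        elif key.family == "ispc":
            pair_values = metrics.ispc[key.qualifier]
            pairs = registry.ispc_pairs[key.grouping]
            vals = [
                pair_values.get((a, b), pair_values.get((b, a), np.nan)) for a, b in pairs
            ]
            v = float(np.mean(vals))
        else:  # pragma: no cover - registry construction guards families
            raise ValueError(f"unknown family {key.family!r}")
        values[key.name] = v
    return pd.Series(values)
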