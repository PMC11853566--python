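"""Channel layouts: names, unit-sphere positions, region and hemisphere tags.

Regional channel groupings and asymmetry contrasts downstream are derived
from the ``region`` and ``hemisphere`` tags, so any layout carrying a full
set of tags works with the default variable registry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

REGIONS = ("frontal", "central", "parietal", "occipital", "lateral")
HEMISPHERES = ("left", "right", "midline")

# name -> (inclination deg from vertex, azimuth deg: 90 = nasion, 0 = right ear),
# region tag, hemisphere tag.  Angles approximate the extended 10-20 scheme.
_DEFAULT_CHANNELS = [
    ("Fp1", 90, 108, "frontal", "left"),
    ("Fp2", 90, 72, "frontal", "right"),
    ("AFz", 69, 90, "frontal", "midline"),
    ("F7", 90, 144, "lateral", "left"),
    ("F3", 49, 119, "frontal", "left"),
    ("Fz", 46, 90, "frontal", "midline"),
    ("F4", 49, 61, "frontal", "right"),
    ("F8", 90, 36, "lateral", "right"),
    ("FC5", 69, 152, "lateral", "left"),
    ("FC1", 31, 112, "frontal", "left"),
    ("FC2", 31, 68, "frontal", "right"),
    ("FC6", 69, 28, "lateral", "right"),
    ("T7", 90, 180, "lateral", "left"),
    ("C3", 46, 180, "central", "left"),
    ("Cz", 0, 0, "central", "midline"),
    ("C4", 46, 0, "central", "right"),
    ("T8", 90, 0, "lateral", "right"),
    ("CP5", 69, 208, "lateral", "left"),
    ("CP1", 31, 248, "central", "left"),
    ("CP2", 31, 292, "central", "right"),
    ("CP6", 69, 332, "lateral", "right"),
    ("P7", 90, 216, "lateral", "left"),
    ("P3", 49, 241, "parietal", "left"),
    ("Pz", 46, 270, "parietal", "midline"),
    ("P4", 49, 299, "parietal", "right"),
    ("P8", 90, 324, "lateral", "right"),
    ("PO3", 69, 255, "parietal", "left"),
    ("POz", 69, 270, "parietal", "midline"),
    ("PO4", 69, 285, "parietal", "right"),
    ("O1", 90, 252, "occipital", "left"),
    ("Oz", 90, 270, "occipital", "midline"),
    ("O2", 90, 288, "occipital", "right"),
]


def _sph_to_cart(incl_deg: float, az_deg: float) -> tuple[float, float, float]:
    incl = np.deg2rad(incl_deg)
    az = np.deg2rad(az_deg)
    return (
        float(np.sin(incl) * np.cos(az)),
        float(np.sin(incl) * np.sin(az)),
        float(np.cos(incl)),
    )


@dataclass(frozen=True)
class ChannelLayout:
    """Immutable channel montage description.

    Parameters
    ----------
    names : tuple of str
        Channel labels, unique.
    positions : ndarray, shape (n_channels, 3)
        Unit-norm cartesian positions on the scalp sphere.
    region : tuple of str
        One region tag per channel, drawn from :data:`REGIONS`.
    hemisphere : tuple of str
        One hemisphere tag per channel, drawn from :data:`HEMISPHERES`.
    """

    names: tuple[str, ...]
    positions: np.ndarray = field(repr=False)
    region: tuple[str, ...]
    hemisphere: tuple[str, ...]

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.shape != (len(self.names), 3):
            raise ValueError("positions must be (n_channels, 3)")
        norms = np.linalg.norm(pos, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise ValueError("channel positions must have unit norm")
        if len(set(self.names)) != len(self.names):
            raise ValueError("channel names must be unique")
        for tag in self.region:
            if tag not in REGIONS:
                raise ValueError(f"unknown region tag {tag!r}")
        for tag in self.hemisphere:
            if tag not in HEMISPHERES:
                raise ValueError(f"unknown hemisphere tag {tag!r}")
        if len(self.region) != len(self.names) or len(self.hemisphere) != len(self.names):
            raise ValueError("region/hemisphere tags must cover all channels")
        object.__setattr__(self, "positions", pos)

    @property
    def n_channels(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def select(self, region: set[str] | None = None, hemisphere: set[str] | None = None) -> list[str]:
        """Channel names matching the given region and/or hemisphere tag sets."""
        out = []
        for name, reg, hemi in zip(self.names, self.region, self.hemisphere):
            if region is not None and reg not in region:
                continue
            if hemisphere is not None and hemi not in hemisphere:
                continue
            out.append(name)
        return out


def default_layout() -> ChannelLayout:
    """The 32-channel extended 10-20 layout used throughout by default."""
    names = tuple(c[0] for c in _DEFAULT_CHANNELS)
    positions = np.array([_sph_to_cart(c[1], c[2]) for c in _DEFAULT_CHANNELS])
    region = tuple(c[3] for c in _DEFAULT_CHANNELS)
    hemisphere = tuple(c[4] for c in _DEFAULT_CHANNELS)
    return ChannelLayout(names=names, positions=positions, region=region, hemisphere=hemisphere)


def regional_groups(layout: ChannelLayout) -> dict[str, list[str]]:
    """The 13 regional channel groups, as name -> member channel names.

    Raises
    ------
    ValueError
        If any group resolves to zero channels on this layout.
    """
    L, R, LR = {"left"}, {"right"}, {"left", "right", "midline"}
    groups = {
        "frontal-left": layout.select({"frontal"}, L),
        "frontal-right": layout.select({"frontal"}, R),
        "centroparietal-left": layout.select({"central", "parietal"}, L),
        "centroparietal-right": layout.select({"central", "parietal"}, R),
        "occipitoparietal-left": layout.select({"parietal", "occipital"}, L),
        "occipitoparietal-right": layout.select({"parietal", "occipital"}, R),
        "frontal": layout.select({"frontal"}, LR),
        "occipital": layout.select({"occipital"}, LR),
        "central": layout.select({"central"}, LR),
        "lateral-left": layout.select({"lateral"}, L),
        "lateral-right": layout.select({"lateral"}, R),
        "hemisphere-left": layout.select(None, L),
        "hemisphere-right": layout.select(None, R),
    }
    for name, members in groups.items():
        if not members:
            raise ValueError(f"channel group {name!r} resolves to zero channels")
    return groups


# Asymmetry contrasts: name -> (minuend regional group, subtrahend regional group)
ASYMMETRY_CONTRASTS = {
    "asym-interhemispheric": ("hemisphere-left", "hemisphere-right"),
    "asym-rostrocaudal-left": ("frontal-left", "occipitoparietal-left"),
    "asym-rostrocaudal-right": ("frontal-right", "occipitoparietal-right"),
    "asym-mediolateral-left": ("centroparietal-left", "lateral-left"),
    "asym-mediolateral-right": ("centroparietal-right", "lateral-right"),
}


def _pairs_within(chs: list[str]) -> list[tuple[str, str]]:
    return [(a, b) for i, a in enumerate(chs) for b in chs[i + 1 :]]


def ispc_contrasts(layout: ChannelLayout) -> dict[str, list[tuple[str, str]]]:
    """Seven channel-pair sets over which ISPC values are averaged."""
    left = layout.select(None, {"left"})
    right = layout.select(None, {"right"})
    frontal = layout.select({"frontal"})
    posterior = layout.select({"parietal", "occipital"})
    occipital = layout.select({"occipital"})
    all_names = list(layout.names)

    # Homologous pairs by 10-20 convention: odd index <-> even index labels.
    homologous = []
    for name in left:
        if name[-1].isdigit():
            mate = name[:-1] + str(int(name[-1]) + 1)
            if mate in right:
                homologous.append((name, mate))

    contrasts = {
        "longrange-frontback": [(f, o) for f in frontal for o in occipital],
        "interhemispheric-homologous": homologous,
        "intra-left": _pairs_within(left),
        "intra-right": _pairs_within(right),
        "frontal-local": _pairs_within(frontal),
        "posterior-local": _pairs_within(posterior),
        "global": _pairs_within(all_names),
    }
    for name, pairs in contrasts.items():
        if not pairs:
            raise ValueError(f"ISPC contrast {name!r} resolves to zero channel pairs")
    return contrasts
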