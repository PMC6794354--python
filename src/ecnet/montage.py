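"""Scalp montage: channel names, idealized unit-sphere positions, region and
hemisphere labels.

The analysis montage has 29 channels grouped into eleven cortical regions
(prefrontal through midline occipital).  The reference (CPz) and ground (AFz)
sites are not analysis channels and are not part of the montage.

Positions are idealized: the 10-20 outer ring (Fp1/2, F7/8, T7/8, P7/8, O1/2
and Fpz) lies on the equator of a unit sphere, the midline and central rows sit
at 45 degrees from the vertex, and intermediate 10-10 sites are spherical
midpoints of their flanking 10-20 sites.  No individual head geometry is
implied; every result that depends on electrode geometry (the surface
Laplacian in particular) inherits this idealization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: region label -> channels, in anterior-to-posterior reading order
REGIONS: dict[str, tuple[str, ...]] = {
    "PFC": ("Fp1", "Fp2"),
    "mPFC": ("Fpz",),
    "VLPFC": ("F7", "F8"),
    "DLPFC": ("F3", "F4"),
    "FC": ("FC5", "FC1", "FC2", "FC6"),
    "mFC": ("Fz", "Cz"),
    "TC": ("T7", "T8", "P7", "P8"),
    "PC": ("C3", "C4", "CP5", "CP1", "CP2", "CP6", "P3", "P4"),
    "mPC": ("Pz",),
    "OC": ("O1", "O2"),
    "mOC": ("POz",),
}

#: canonical channel order (rows of every adjacency matrix)
CHANNELS: tuple[str, ...] = (
    "Fp1", "Fpz", "Fp2",
    "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6",
    "T7", "C3", "Cz", "C4", "T8",
    "CP5", "CP1", "CP2", "CP6",
    "P7", "P3", "Pz", "P4", "P8",
    "O1", "POz", "O2",
)

N_CHANNELS = len(CHANNELS)


def channel_hemisphere(name: str) -> str:
    """Hemisphere from the 10-20 naming rule: odd = left, even = right,
    z-suffix = midline."""
    if name.lower().endswith("z"):
        return "midline"
    digits = "".join(ch for ch in name if ch.isdigit())
    if not digits:
        raise ValueError(f"cannot infer hemisphere for channel {name!r}")
    return "left" if int(digits) % 2 == 1 else "right"


def _pol(gamma_deg: float, theta_deg: float) -> np.ndarray:
    """Unit vector from inclination gamma (from vertex) and azimuth theta
    (from the front midline, positive toward the left).  Frame: +x right,
    +y front, +z up."""
    g = np.deg2rad(gamma_deg)
    t = np.deg2rad(theta_deg)
    return np.array([-np.sin(g) * np.sin(t), np.sin(g) * np.cos(t), np.cos(g)])


def _mid(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    v = a + b
    return v / np.linalg.norm(v)


def _build_positions() -> dict[str, np.ndarray]:
    p: dict[str, np.ndarray] = {}
    base = {
        "Cz": (0.0, 0.0),
        "Fpz": (90.0, 0.0), "Fz": (45.0, 0.0), "Pz": (45.0, 180.0),
        "Fp1": (90.0, 18.0), "Fp2": (90.0, -18.0),
        "F7": (90.0, 54.0), "F8": (90.0, -54.0),
        "T7": (90.0, 90.0), "T8": (90.0, -90.0),
        "P7": (90.0, 126.0), "P8": (90.0, -126.0),
        "O1": (90.0, 162.0), "O2": (90.0, -162.0),
        "C3": (45.0, 90.0), "C4": (45.0, -90.0),
    }
    for name, (g, t) in base.items():
        p[name] = _pol(g, t)
    oz = _pol(90.0, 180.0)  # construction aid only, not a montage channel
    p["F3"] = _mid(p["F7"], p["Fz"])
    p["F4"] = _mid(p["F8"], p["Fz"])
    p["P3"] = _mid(p["P7"], p["Pz"])
    p["P4"] = _mid(p["P8"], p["Pz"])
    p["FC5"] = _mid(p["F7"], p["C3"])
    p["FC6"] = _mid(p["F8"], p["C4"])
    p["FC1"] = _mid(p["Fz"], p["C3"])
    p["FC2"] = _mid(p["Fz"], p["C4"])
    p["CP5"] = _mid(p["P7"], p["C3"])
    p["CP6"] = _mid(p["P8"], p["C4"])
    p["CP1"] = _mid(p["Pz"], p["C3"])
    p["CP2"] = _mid(p["Pz"], p["C4"])
    p["POz"] = _mid(p["Pz"], oz)
    return p


@dataclass(frozen=True)
class Montage:
    """Ordered channel set with positions, region and hemisphere labels."""

    channels: tuple[str, ...]
    positions: dict[str, np.ndarray] = field(repr=False)
    region: dict[str, str] = field(repr=False)
    hemisphere: dict[str, str] = field(repr=False)

    def __post_init__(self) -> None:
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("duplicate channel names in montage")
        for ch in self.channels:
            if ch not in self.positions:
                raise ValueError(f"channel {ch!r} has no position")
            if ch not in self.region:
                raise ValueError(f"channel {ch!r} has no region label")
            if ch not in self.hemisphere:
                raise ValueError(f"channel {ch!r} has no hemisphere label")

    def __len__(self) -> int:
        return len(self.channels)

    def index(self, name: str) -> int:
        return self.channels.index(name)

    def position_array(self) -> np.ndarray:
        """(n_channels, 3) unit-sphere coordinates in channel order."""
        return np.array([self.positions[ch] for ch in self.channels])

    def subset(self, channels: list[str] | tuple[str, ...]) -> "Montage":
        missing = [c for c in channels if c not in self.channels]
        if missing:
            raise ValueError(f"channels not in montage: {missing}")
        return Montage(
            channels=tuple(channels),
            positions={c: self.positions[c] for c in channels},
            region={c: self.region[c] for c in channels},
            hemisphere={c: self.hemisphere[c] for c in channels},
        )


def default_montage() -> Montage:
    """The packaged 29-channel analysis montage."""
    region = {ch: reg for reg, chs in REGIONS.items() for ch in chs}
    return Montage(
        channels=CHANNELS,
        positions=_build_positions(),
        region=region,
        hemisphere={ch: channel_hemisphere(ch) for ch in CHANNELS},
    )
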