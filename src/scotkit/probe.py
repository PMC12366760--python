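"""High-density hexagonal SCOT probe geometry.

The simulated array has 7 sources and 16 detectors whose source-detector
separations fall in three classes: 19 mm (nearest), 33 mm (second nearest,
19*sqrt(3)) and ~50 mm (third nearest, 19*sqrt(7)).  Only the 19 mm and
33 mm classes form usable channels (longer separations drop below camera
noise in practice), giving exactly 50 channels.

Geometry: sources sit on a triangular lattice of pitch 38 mm (= 2 x 19);
detectors sit at lattice-edge midpoints — the 12 midpoints interior to the
7-source flower plus 4 midpoints of outward-slanted edges.  Each detector
is then 19 mm from its two edge endpoints and 19*sqrt(3) mm from the apex
sources of the triangles flanking its edge, which reproduces the stated
separation classes exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

#: accepted separation classes (mm) and the matching tolerance
SEPARATION_CLASSES = (19.0, 19.0 * np.sqrt(3.0))
SEPARATION_TOL = 0.5


class ProbeConfigurationError(ValueError):
    """Raised when a probe cannot realize the required channel set."""


@dataclass(frozen=True)
class Channel:
    source_id: str
    detector_id: str
    separation: float


@dataclass
class Probe:
    """Labeled optode coordinates and the valid source-detector channels."""

    sources: dict[str, np.ndarray]
    detectors: dict[str, np.ndarray]
    channels: list[Channel]

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def channel_positions(self) -> list[tuple[np.ndarray, np.ndarray]]:
        """(source_xyz, detector_xyz) per channel, in channel order."""
        return [
            (self.sources[c.source_id], self.detectors[c.detector_id])
            for c in self.channels
        ]

    def separations(self) -> np.ndarray:
        return np.array([c.separation for c in self.channels])

    def translated(self, offset) -> "Probe":
        off = np.asarray(offset, float)
        return Probe(
            {k: v + off for k, v in self.sources.items()},
            {k: v + off for k, v in self.detectors.items()},
            list(self.channels),
        )

    def to_csv(self, path: str | Path) -> None:
        rows = [
            {"label": k, "type": "S", "x_mm": v[0], "y_mm": v[1], "z_mm": v[2]}
            for k, v in self.sources.items()
        ] + [
            {"label": k, "type": "D", "x_mm": v[0], "y_mm": v[1], "z_mm": v[2]}
            for k, v in self.detectors.items()
        ]
        pd.DataFrame(rows).to_csv(path, index=False)

    def channels_to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            [
                {
                    "channel_id": i,
                    "source_id": c.source_id,
                    "detector_id": c.detector_id,
                    "separation_mm": c.separation,
                }
                for i, c in enumerate(self.channels)
            ]
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "Probe":
        """Load an optode layout CSV (label, type{S,D}, x_mm, y_mm, z_mm)."""
        df = pd.read_csv(path)
        sources, detectors = {}, {}
        for _, row in df.iterrows():
            xyz = np.array([row["x_mm"], row["y_mm"], row["z_mm"]], float)
            (sources if str(row["type"]).upper() == "S" else detectors)[
                str(row["label"])
            ] = xyz
        return cls(sources, detectors, _form_channels(sources, detectors))


def _form_channels(
    sources: dict[str, np.ndarray], detectors: dict[str, np.ndarray]
) -> list[Channel]:
    """All SD pairs whose separation matches an accepted class."""
    channels = []
    for sid, sp in sources.items():
        for did, dp in detectors.items():
            sep = float(np.linalg.norm(sp - dp))
            if any(abs(sep - c) <= SEPARATION_TOL for c in SEPARATION_CLASSES):
                channels.append(Channel(sid, did, sep))
    return channels


def build_hex_probe(
    pitch: float = 19.0, n_sources: int = 7, n_detectors: int = 16
) -> Probe:
    """Construct the 7-source / 16-detector hexagonal probe.

    ``pitch`` is the nearest source-detector separation (mm).  The probe is
    centered at the origin on the surface z = 0.  Raises
    :class:`ProbeConfigurationError` if the requested optode counts cannot
    realize the 50-channel configuration.
    """
    if n_sources != 7 or n_detectors != 16:
        raise ProbeConfigurationError(
            "the hexagonal layout is defined for 7 sources and 16 detectors; "
            f"got {n_sources} sources, {n_detectors} detectors"
        )
    a = 2.0 * pitch  # source lattice constant (38 mm at default pitch)
    ring = [
        a * np.array([np.cos(np.deg2rad(60 * k)), np.sin(np.deg2rad(60 * k)), 0.0])
        for k in range(6)
    ]
    sources = {"S1": np.zeros(3)}
    for k, v in enumerate(ring):
        sources[f"S{k + 2}"] = v
    detectors: dict[str, np.ndarray] = {}
    # 6 midpoints of center-to-ring edges + 6 midpoints of ring-to-ring edges
    for k in range(6):
        detectors[f"D{k + 1}"] = 0.5 * ring[k]
    for k in range(6):
        detectors[f"D{k + 7}"] = 0.5 * (ring[k] + ring[(k + 1) % 6])
    # 4 outward-slanted edge midpoints: from ring source k along the
    # direction of ring vector k+1 (each adds one 19 mm and one 33 mm pair)
    for j, k in enumerate((0, 1, 3, 4)):
        detectors[f"D{j + 13}"] = ring[k] + 0.5 * ring[(k + 1) % 6]
    channels = _form_channels(sources, detectors)
    if len(channels) != 50:
        seps = sorted(
            round(float(np.linalg.norm(sp - dp)), 2)
            for sp in sources.values()
            for dp in detectors.values()
        )
        raise ProbeConfigurationError(
            f"expected 50 channels, formed {len(channels)}; "
            f"separation classes present: {sorted(set(seps))}"
        )
    return Probe(sources, detectors, channels)
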