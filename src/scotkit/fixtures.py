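"""Deterministic generation of the validation fixtures.

Writes the phantom configurations of the three linearity experiments, the
hexagonal probe layout, and the six-layer head-tissue slab whose optical
and dynamic properties (skin, skull, dura mater, CSF, gray matter, white
matter) are the standard head-model values used with the effective-
absorption fluence solver.
"""

from __future__ import annotations

import json
from pathlib import Path

from .config import InclusionConfig, RunConfig
from .config import save_config
from .medium import VoxelGrid
from .montecarlo import VoxelMedium
from .probe import build_hex_probe

#: head-tissue layers: (name, thickness_mm, mua 1/mm, musp 1/mm, alphaDb mm^2/s)
HEAD_SLAB_LAYERS = [
    ("skin", 4.0, 0.0191, 0.65934, 1e-6),
    ("skull", 7.0, 0.0136, 0.85914, 1e-6),
    ("dura", 1.0, 0.0191, 0.65934, 1e-6),
    ("csf", 2.0, 0.0026, 0.00999, 1e-6),
    ("gray", 4.0, 0.0186, 1.0989, 6e-6),
    ("white", 42.0, 0.0186, 0.85914, 6e-6),
]

FIXTURE_KINDS = ("inclusion_small", "inclusion_large", "spatial_regions", "hex_probe", "head_slab")


def layered_slab_medium(
    grid: VoxelGrid | None = None, wavelength_nm: float = 852.0
) -> VoxelMedium:
    """Six-layer voxelized head-tissue slab on ``grid`` (default 60^3 mm, 2 mm)."""
    if grid is None:
        grid = VoxelGrid((-30.0, -30.0, 0.0), (2.0, 2.0, 2.0), (30, 30, 30))
    layers = [(t, a, sp, d) for _, t, a, sp, d in HEAD_SLAB_LAYERS]
    return VoxelMedium.layered(grid, layers, wavelength_nm=wavelength_nm)


def make_fixtures(kind: str, out_dir: str | Path) -> list[Path]:
    """Write the fixture files for ``kind`` into ``out_dir``; returns paths.

    All fixtures are deterministic (no RNG involved).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if kind == "inclusion_small" or kind == "inclusion_large":
        size = (10.0, 10.0, 10.0) if kind == "inclusion_small" else (60.0, 50.0, 40.0)
        cfg = RunConfig(
            inclusions=[InclusionConfig(center=(15.0, 0.0, 30.0), size=size, rDb=2.0)]
        )
        p = out / f"{kind}.json"
        save_config(cfg, p)
        written.append(p)
    elif kind == "spatial_regions":
        cfg = RunConfig(
            inclusions=[
                InclusionConfig(center=(0.0, 0.0, 30.0), size=(30.0, 50.0, 40.0), rDb=2.0),
                InclusionConfig(center=(30.0, 0.0, 30.0), size=(30.0, 50.0, 40.0), rDb=2.0),
            ]
        )
        p = out / "spatial_regions.json"
        save_config(cfg, p)
        written.append(p)
    elif kind == "hex_probe":
        probe = build_hex_probe()
        p1 = out / "hex_probe_optodes.csv"
        probe.to_csv(p1)
        p2 = out / "hex_probe_channels.csv"
        probe.channels_to_csv(p2)
        written += [p1, p2]
    elif kind == "head_slab":
        p = out / "head_slab.json"
        p.write_text(
            json.dumps(
                {
                    "wavelength_nm": 852.0,
                    "n": 1.33,
                    "layers": [
                        {
                            "name": nm,
                            "thickness_mm": t,
                            "mua": a,
                            "musp": sp,
                            "alphaDb": d,
                        }
                        for nm, t, a, sp, d in HEAD_SLAB_LAYERS
                    ],
                },
                indent=2,
            )
            + "\n"
        )
        written.append(p)
    else:
        raise ValueError(f"unknown fixture kind {kind!r}; expected one of {FIXTURE_KINDS}")
    return written
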