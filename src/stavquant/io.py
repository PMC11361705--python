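"""Reading and writing stacks, sidecars and scene configurations.

Stacks travel as multi-page TIFF (axes CZYX, one page series per
channel) with a JSON sidecar next to them carrying the physical
calibration, channel labels, seed and — for synthetic data — the
ground truth, so a rendered scene round-trips losslessly through disk.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .scene import (
    GranuleSpec,
    GroundTruth,
    ImageStack,
    OpticsSpec,
    PoreRingSpec,
    SceneSpec,
)

__all__ = ["write_stack", "read_stack", "scene_from_yaml", "scene_to_yaml"]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_stack(
    stack: ImageStack,
    path,
    truth: GroundTruth | None = None,
    metadata: dict | None = None,
) -> Path:
    """Write a stack as TIFF plus a JSON sidecar; returns the TIFF path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(
        path,
        stack.data.astype(np.float32),
        photometric="minisblack",
        metadata={"axes": "CZYX"},
    )
    sidecar = {
        "channels": list(stack.channels),
        "z_step_nm": stack.z_step,
        "pixel_size_xy_nm": stack.pixel_size_xy,
    }
    if truth is not None:
        sidecar["seed"] = truth.seed
        sidecar["ground_truth"] = {
            "granules": truth.granules.to_dict(orient="records"),
            "pores": truth.pores.to_dict(orient="records"),
        }
    if metadata:
        sidecar["metadata"] = metadata
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def read_stack(path) -> tuple[ImageStack, GroundTruth | None, dict]:
    """Read a TIFF stack and its sidecar; returns (stack, truth, metadata)."""
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim == 3:  # single channel written without C axis
        data = data[None]
    sidecar_file = _sidecar_path(path)
    if not sidecar_file.exists():
        raise FileNotFoundError(
            f"calibration sidecar {sidecar_file} missing; stacks need physical calibration"
        )
    sidecar = json.loads(sidecar_file.read_text())
    stack = ImageStack(
        data=data,
        channels=tuple(sidecar["channels"]),
        z_step=float(sidecar["z_step_nm"]),
        pixel_size_xy=float(sidecar["pixel_size_xy_nm"]),
    )
    truth = None
    if "ground_truth" in sidecar:
        gt = sidecar["ground_truth"]
        truth = GroundTruth(
            granules=pd.DataFrame(gt["granules"]),
            pores=pd.DataFrame(gt["pores"]),
            seed=int(sidecar.get("seed", 0)),
        )
    return stack, truth, sidecar.get("metadata", {})


# --------------------------------------------------------------------------
# Scene configuration (YAML)

def scene_from_yaml(path) -> SceneSpec:
    """Build a SceneSpec from a YAML scene configuration file."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    optics = OpticsSpec(**doc.get("optics", {}))
    granules = tuple(
        GranuleSpec(
            center=tuple(g["center"]),
            radius=float(g["radius"]),
            channel=str(g["channel"]),
            labelling_mode=g.get("labelling_mode", "volume"),
            shell_fraction=float(g.get("shell_fraction", 1.0)),
            amplitude=float(g.get("amplitude", 100.0)),
        )
        for g in doc.get("granules", [])
    )
    rings = tuple(
        PoreRingSpec(
            nucleus_center=tuple(r["nucleus_center"]),
            nucleus_radius=float(r["nucleus_radius"]),
            n_pores=int(r["n_pores"]),
            pore_amplitude=float(r.get("pore_amplitude", 20000.0)),
            channel_scale={str(k): float(v) for k, v in r.get("channel_scale", {}).items()},
            phase=float(r.get("phase", 0.0)),
        )
        for r in doc.get("pore_rings", [])
    )
    return SceneSpec(
        shape=tuple(doc.get("shape", (48, 256, 256))),
        channels=tuple(doc.get("channels", ("HA", "strep"))),
        granules=granules,
        pore_rings=rings,
        optics=optics,
        seed=int(doc.get("seed", 0)),
    )


def scene_to_yaml(scene: SceneSpec, path) -> None:
    """Serialise a SceneSpec to YAML (inverse of :func:`scene_from_yaml`)."""
    doc = {
        "shape": list(scene.shape),
        "channels": list(scene.channels),
        "seed": scene.seed,
        "optics": {
            "pixel_size_xy": scene.optics.pixel_size_xy,
            "z_step": scene.optics.z_step,
            "psf_sigma_xy": scene.optics.psf_sigma_xy,
            "psf_sigma_z": scene.optics.psf_sigma_z,
            "background": scene.optics.background,
            "read_noise_sd": scene.optics.read_noise_sd,
        },
        "granules": [
            {
                "center": list(g.center),
                "radius": g.radius,
                "channel": g.channel,
                "labelling_mode": g.labelling_mode,
                "shell_fraction": g.shell_fraction,
                "amplitude": g.amplitude,
            }
            for g in scene.granules
        ],
        "pore_rings": [
            {
                "nucleus_center": list(r.nucleus_center),
                "nucleus_radius": r.nucleus_radius,
                "n_pores": r.n_pores,
                "pore_amplitude": r.pore_amplitude,
                "channel_scale": dict(r.channel_scale),
                "phase": r.phase,
            }
            for r in scene.pore_rings
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
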