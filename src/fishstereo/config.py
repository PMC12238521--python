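"""Rig/port configuration file I/O (YAML or JSON by extension).

Schema::

    model: parallel            # single | parallel | tilted | none
    image_size: [1280, 720]
    cameras:
      left:
        intrinsics: {f_mm, dx_mm, dy_mm, skew, u0, v0, k1, k2}
        extrinsics: {R: [9 row-major], t: [3]}
        port: {d_mm, T_mm, n_air, n_glass, n_water, tilt_deg}
      right: ...

Angles are degrees at this boundary and radians inside the library; all
lengths are mm.  ``model: none`` disables refraction correction (the
"measure the raw underwater pixels" baseline).
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import yaml

from .camera import CameraExtrinsics, CameraIntrinsics
from .refraction import FlatPort, RefractionModel
from .stereo import RigCamera, StereoRig

__all__ = ["load_rig", "save_rig", "parse_model"]


def parse_model(name: str) -> RefractionModel | None:
    """Map a config string to a refraction model; 'none' -> None."""
    name = name.strip().lower()
    if name == "none":
        return None
    try:
        return RefractionModel(name)
    except ValueError:
        valid = [m.value for m in RefractionModel] + ["none"]
        raise ValueError(f"unknown model '{name}', expected one of {valid}") from None


def _camera_to_dict(cam: RigCamera) -> dict:
    k = cam.intrinsics
    return {
        "intrinsics": {
            "f_mm": k.focal_length_mm,
            "dx_mm": k.dx_mm,
            "dy_mm": k.dy_mm,
            "skew": k.skew,
            "u0": k.principal_point[0],
            "v0": k.principal_point[1],
            "k1": k.radial_distortion[0],
            "k2": k.radial_distortion[1],
        },
        "extrinsics": {
            "R": [float(v) for v in cam.extrinsics.rotation.ravel()],
            "t": [float(v) for v in cam.extrinsics.translation],
        },
        "port": {
            "d_mm": cam.port.d_mm,
            "T_mm": cam.port.t_mm,
            "n_air": cam.port.n_air,
            "n_glass": cam.port.n_glass,
            "n_water": cam.port.n_water,
            "tilt_deg": math.degrees(cam.port.tilt_rad),
        },
    }


def _camera_from_dict(d: dict) -> RigCamera:
    ki = d["intrinsics"]
    intr = CameraIntrinsics(
        focal_length_mm=float(ki["f_mm"]),
        dx_mm=float(ki["dx_mm"]),
        dy_mm=float(ki["dy_mm"]),
        skew=float(ki.get("skew", 0.0)),
        principal_point=(float(ki["u0"]), float(ki["v0"])),
        radial_distortion=(float(ki.get("k1", 0.0)), float(ki.get("k2", 0.0))),
    )
    ke = d["extrinsics"]
    ext = CameraExtrinsics(
        rotation=np.asarray(ke["R"], dtype=float).reshape(3, 3),
        translation=np.asarray(ke["t"], dtype=float),
    )
    kp = d["port"]
    port = FlatPort(
        d_mm=float(kp["d_mm"]),
        t_mm=float(kp["T_mm"]),
        n_air=float(kp.get("n_air", 1.0)),
        n_glass=float(kp.get("n_glass", 1.6)),
        n_water=float(kp.get("n_water", 1.33)),
        tilt_rad=math.radians(float(kp.get("tilt_deg", 0.0))),
    )
    return RigCamera(intrinsics=intr, extrinsics=ext, port=port)


def save_rig(
    rig: StereoRig, path, model: RefractionModel | None = RefractionModel.PARALLEL
) -> None:
    """Write a rig (and the refraction-model choice) to YAML/JSON."""
    doc = {
        "model": model.value if model is not None else "none",
        "image_size": list(rig.image_size),
        "cameras": {
            "left": _camera_to_dict(rig.left),
            "right": _camera_to_dict(rig.right),
        },
    }
    path = Path(path)
    with open(path, "w") as fh:
        if path.suffix.lower() == ".json":
            json.dump(doc, fh, indent=1)
        else:
            yaml.safe_dump(doc, fh, sort_keys=False)


def load_rig(path) -> tuple[StereoRig, RefractionModel | None]:
    """Read a rig config; returns (rig, model) where model may be None."""
    path = Path(path)
    with open(path) as fh:
        doc = json.load(fh) if path.suffix.lower() == ".json" else yaml.safe_load(fh)
    rig = StereoRig(
        left=_camera_from_dict(doc["cameras"]["left"]),
        right=_camera_from_dict(doc["cameras"]["right"]),
        image_size=tuple(doc.get("image_size", (1280, 720))),
    )
    return rig, parse_model(str(doc.get("model", "parallel")))
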