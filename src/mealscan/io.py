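"""Readers and writers for point clouds and depth frames.

Point clouds travel as PLY (ASCII or binary, via trimesh) or PCD (ASCII,
plus binary reading); depth frames as 16-bit single-channel PNG in
millimeters or NPZ rasters, with a JSON intrinsics/timestamp sidecar.
"""

from __future__ import annotations

import json
import re
import struct
from pathlib import Path
from typing import Optional

import numpy as np
import trimesh
from PIL import Image

from .geometry import CameraIntrinsics, DepthFrame, PointCloud


class DataFormatError(ValueError):
    """Raised for malformed or unsupported input files."""


# ---------------------------------------------------------------------------
# PLY
# ---------------------------------------------------------------------------


def save_ply(cloud: PointCloud, path, binary: bool = False) -> None:
    colors = None
    if cloud.colors is not None:
        colors = np.column_stack(
            [cloud.colors, np.full(len(cloud), 255, dtype=np.uint8)]
        )
    tm = trimesh.PointCloud(cloud.points, colors=colors)
    encoding = "binary" if binary else "ascii"
    data = trimesh.exchange.ply.export_ply(tm, encoding=encoding)
    Path(path).write_bytes(data)


def load_ply(path) -> PointCloud:
    try:
        tm = trimesh.load(str(path), file_type="ply", process=False)
    except Exception as exc:  # trimesh raises various types on bad input
        raise DataFormatError(f"cannot parse PLY {path}: {exc}") from exc
    vertices = np.asarray(tm.vertices, dtype=np.float64)
    if vertices.size == 0:
        return PointCloud.empty()
    colors = None
    if getattr(tm, "colors", None) is not None and len(tm.colors):
        colors = np.asarray(tm.colors)[:, :3].astype(np.uint8)
    return PointCloud(vertices, colors)


# ---------------------------------------------------------------------------
# PCD (hand-rolled: no PCD library in the stack)
# ---------------------------------------------------------------------------


def save_pcd(cloud: PointCloud, path) -> None:
    """Write an ASCII PCD v0.7 file (x y z, plus packed rgb if colored)."""
    with_rgb = cloud.colors is not None
    fields = "x y z rgb" if with_rgb else "x y z"
    sizes = "4 4 4 4" if with_rgb else "4 4 4"
    types = "F F F F" if with_rgb else "F F F"
    counts = "1 1 1 1" if with_rgb else "1 1 1"
    n = len(cloud)
    lines = [
        "# .PCD v0.7 - Point Cloud Data file format",
        "VERSION 0.7",
        f"FIELDS {fields}",
        f"SIZE {sizes}",
        f"TYPE {types}",
        f"COUNT {counts}",
        f"WIDTH {n}",
        "HEIGHT 1",
        "VIEWPOINT 0 0 0 1 0 0 0",
        f"POINTS {n}",
        "DATA ascii",
    ]
    for i in range(n):
        x, y, z = cloud.points[i]
        if with_rgb:
            r, g, b = (int(c) for c in cloud.colors[i])
            packed = (r << 16) | (g << 8) | b
            rgbf = struct.unpack("f", struct.pack("I", packed))[0]
            lines.append(f"{x:.9g} {y:.9g} {z:.9g} {rgbf:.9g}")
        else:
            lines.append(f"{x:.9g} {y:.9g} {z:.9g}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_pcd(path) -> PointCloud:
    """Read ASCII or binary PCD with float32 x/y/z and optional rgb."""
    raw = Path(path).read_bytes()
    header_end = 0
    header: dict[str, str] = {}
    for match in re.finditer(rb"([A-Z_#][^\n]*)\n", raw):
        line = match.group(1).decode("ascii", errors="replace")
        header_end = match.end()
        if line.startswith("#"):
            continue
        key, _, value = line.partition(" ")
        header[key] = value
        if key == "DATA":
            break
    for needed in ("FIELDS", "TYPE", "SIZE", "POINTS", "DATA"):
        if needed not in header:
            raise DataFormatError(f"PCD header missing {needed}")
    fields = header["FIELDS"].split()
    types = header["TYPE"].split()
    sizes = [int(s) for s in header["SIZE"].split()]
    n = int(header["POINTS"])
    for axis in ("x", "y", "z"):
        if axis not in fields:
            raise DataFormatError(f"PCD lacks field {axis}")
    if header["DATA"] == "ascii":
        text = raw[header_end:].decode("ascii", errors="replace")
        values = np.loadtxt(text.strip().splitlines(), dtype=np.float64, ndmin=2)
        if values.shape != (n, len(fields)):
            raise DataFormatError("PCD ascii data shape mismatch")
        cols = {f: values[:, i] for i, f in enumerate(fields)}
    elif header["DATA"] == "binary":
        fmt_map = {("F", 4): "f", ("F", 8): "d", ("U", 4): "I", ("I", 4): "i"}
        np_fields = []
        for f, t, s in zip(fields, types, sizes):
            fmt = fmt_map.get((t, s))
            if fmt is None:
                raise DataFormatError(f"unsupported PCD field type {t}{s}")
            np_fields.append((f, fmt))
        dtype = np.dtype(np_fields)
        rec = np.frombuffer(raw[header_end:], dtype=dtype, count=n)
        cols = {f: rec[f].astype(np.float64) for f in fields}
    else:
        raise DataFormatError(f"unsupported PCD DATA mode {header['DATA']!r}")
    points = np.column_stack([cols["x"], cols["y"], cols["z"]])
    colors = None
    if "rgb" in fields:
        packed = np.array(
            [struct.unpack("I", struct.pack("f", v))[0] for v in cols["rgb"]],
            dtype=np.uint32,
        )
        colors = np.column_stack(
            [(packed >> 16) & 255, (packed >> 8) & 255, packed & 255]
        ).astype(np.uint8)
    return PointCloud(points, colors)


def load_cloud(path) -> PointCloud:
    """Dispatch on extension (.ply / .pcd)."""
    suffix = Path(path).suffix.lower()
    if suffix == ".ply":
        return load_ply(path)
    if suffix == ".pcd":
        return load_pcd(path)
    raise DataFormatError(f"unsupported cloud format: {suffix}")


# ---------------------------------------------------------------------------
# Depth frames
# ---------------------------------------------------------------------------


def save_frame(frame: DepthFrame, out_dir, index: int) -> None:
    """Write frame_<index> as depth PNG (uint16 mm), RGB PNG, JSON sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = f"frame_{index:04d}"
    depth_u16 = np.clip(np.round(frame.depth), 0, 65535).astype(np.uint16)
    Image.fromarray(depth_u16).save(out_dir / f"{stem}_depth.png")
    if frame.rgb is not None:
        Image.fromarray(frame.rgb).save(out_dir / f"{stem}_rgb.png")
    meta = {
        "intrinsics": frame.intrinsics.to_dict(),
        "timestamp": frame.timestamp,
    }
    (out_dir / f"{stem}_meta.json").write_text(json.dumps(meta, indent=2))


def load_frame(out_dir, index: int) -> DepthFrame:
    out_dir = Path(out_dir)
    stem = f"frame_{index:04d}"
    meta_path = out_dir / f"{stem}_meta.json"
    if not meta_path.exists():
        raise DataFormatError(f"missing sidecar {meta_path}")
    meta = json.loads(meta_path.read_text())
    depth = np.asarray(
        Image.open(out_dir / f"{stem}_depth.png"), dtype=np.float64
    )
    rgb_path = out_dir / f"{stem}_rgb.png"
    rgb = np.asarray(Image.open(rgb_path)) if rgb_path.exists() else None
    return DepthFrame(
        depth,
        CameraIntrinsics.from_dict(meta["intrinsics"]),
        rgb=rgb,
        timestamp=float(meta.get("timestamp", 0.0)),
    )


def load_frame_sequence(out_dir) -> list[DepthFrame]:
    out_dir = Path(out_dir)
    indices = sorted(
        int(p.stem.split("_")[1]) for p in out_dir.glob("frame_*_meta.json")
    )
    if not indices:
        raise DataFormatError(f"no frames found in {out_dir}")
    return [load_frame(out_dir, i) for i in indices]


def save_frame_npz(frame: DepthFrame, path) -> None:
    arrays = {"depth_mm": frame.depth, "timestamp": np.float64(frame.timestamp)}
    arrays.update({f"K_{k}": np.float64(v) for k, v in frame.intrinsics.to_dict().items()})
    if frame.rgb is not None:
        arrays["rgb"] = frame.rgb
    np.savez(path, **arrays)


def load_frame_npz(path) -> DepthFrame:
    data = np.load(path)
    K = CameraIntrinsics(
        fx=float(data["K_fx"]),
        fy=float(data["K_fy"]),
        cx=float(data["K_cx"]),
        cy=float(data["K_cy"]),
        width=int(data["K_width"]),
        height=int(data["K_height"]),
    )
    rgb = data["rgb"] if "rgb" in data else None
    return DepthFrame(
        data["depth_mm"], K, rgb=rgb, timestamp=float(data["timestamp"])
    )
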