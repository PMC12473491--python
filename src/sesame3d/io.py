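"""Readers and writers for the formats the pipeline touches.

PLY (ASCII and binary little-endian) carries raw and cleaned point clouds;
whitespace-delimited TXT rows ``x y z r g b label`` carry annotated clouds
(the CloudCompare export convention); the trait report is a small CSV with
one plant-level row and one row per leaf.

Readers never reorder points, and round trips are lossless: binary PLY
stores coordinates as float64, TXT stores labels exactly.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np

from .containers import (
    NOISE_INSTANCE,
    FormatError,
    LabeledCloud,
    LeafTraits,
    PointCloud,
    TraitReport,
)

_PLY_TYPES = {
    "char": "i1", "int8": "i1",
    "uchar": "u1", "uint8": "u1",
    "short": "i2", "int16": "i2",
    "ushort": "u2", "uint16": "u2",
    "int": "i4", "int32": "i4",
    "uint": "u4", "uint32": "u4",
    "float": "f4", "float32": "f4",
    "double": "f8", "float64": "f8",
}


class ParseError(FormatError):
    """Malformed text row; carries the 1-based line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


def _parse_ply_header(fh) -> tuple[str, list[tuple[str, int, list[tuple[str, str]]]]]:
    magic = fh.readline().strip()
    if magic != b"ply":
        raise FormatError("not a PLY file (missing 'ply' magic)")
    fmt = None
    elements: list[tuple[str, int, list[tuple[str, str]]]] = []
    while True:
        line = fh.readline()
        if not line:
            raise FormatError("unexpected end of PLY header")
        tokens = line.decode("ascii", "replace").split()
        if not tokens or tokens[0] == "comment":
            continue
        if tokens[0] == "format":
            fmt = tokens[1]
        elif tokens[0] == "element":
            elements.append((tokens[1], int(tokens[2]), []))
        elif tokens[0] == "property":
            if tokens[1] == "list":
                elements[-1][2].append((tokens[-1], "list:" + tokens[2] + ":" + tokens[3]))
            else:
                elements[-1][2].append((tokens[2], tokens[1]))
        elif tokens[0] == "end_header":
            break
    if fmt not in ("ascii", "binary_little_endian"):
        raise FormatError(f"unsupported PLY format {fmt!r}")
    return fmt, elements


def read_ply(path: str | Path) -> PointCloud:
    """Read a PLY point cloud (ASCII or binary little-endian).

    The ``vertex`` element must provide ``x, y, z``; ``red, green, blue``
    are read when present. Row order is preserved.
    """
    path = Path(path)
    with open(path, "rb") as fh:
        fmt, elements = _parse_ply_header(fh)
        vertex = next((e for e in elements if e[0] == "vertex"), None)
        if vertex is None:
            raise FormatError("PLY has no vertex element")
        if elements and elements[0][0] != "vertex":
            raise FormatError("vertex must be the first PLY element")
        _, count, props = vertex
        names = [p[0] for p in props]
        if any(t.startswith("list:") for _, t in props):
            raise FormatError("list properties are not supported on vertices")
        for axis in ("x", "y", "z"):
            if axis not in names:
                raise FormatError(f"PLY vertex element lacks property {axis!r}")
        dtype = np.dtype([(n, "<" + _PLY_TYPES[t]) for n, t in props])
        if fmt == "binary_little_endian":
            data = np.frombuffer(fh.read(dtype.itemsize * count), dtype=dtype, count=count)
        else:
            rows = []
            while len(rows) < count:
                line = fh.readline()
                if not line:
                    raise FormatError("PLY ASCII data ended early")
                if line.strip():
                    rows.append(line.split()[: len(props)])
            data = np.zeros(count, dtype=dtype)
            if count:
                arr = np.array(rows, dtype=np.float64)
                for j, (n, _) in enumerate(props):
                    data[n] = arr[:, j]
        coords = np.stack(
            [data["x"], data["y"], data["z"]], axis=1
        ).astype(np.float64) if count else np.empty((0, 3))
        colors = None
        if all(c in names for c in ("red", "green", "blue")):
            colors = (
                np.stack([data["red"], data["green"], data["blue"]], axis=1)
                if count
                else np.empty((0, 3), dtype=np.uint8)
            )
        return PointCloud(coords, colors)


def write_ply(cloud: PointCloud, path: str | Path) -> None:
    """Write binary little-endian PLY; colors are written iff present.

    Coordinates are stored as float64 so that ``read_ply(write_ply(c))``
    reproduces them bit-exactly.
    """
    path = Path(path)
    fields = [("x", "<f8"), ("y", "<f8"), ("z", "<f8")]
    header = [
        "ply",
        "format binary_little_endian 1.0",
        f"element vertex {len(cloud)}",
        "property double x",
        "property double y",
        "property double z",
    ]
    if cloud.has_colors:
        fields += [("red", "u1"), ("green", "u1"), ("blue", "u1")]
        header += [
            "property uchar red",
            "property uchar green",
            "property uchar blue",
        ]
    header.append("end_header")
    data = np.zeros(len(cloud), dtype=np.dtype(fields))
    for j, axis in enumerate("xyz"):
        data[axis] = cloud.coords[:, j]
    if cloud.has_colors:
        for j, chan in enumerate(("red", "green", "blue")):
            data[chan] = cloud.colors[:, j]
    with open(path, "wb") as fh:
        fh.write(("\n".join(header) + "\n").encode("ascii"))
        fh.write(data.tobytes())


def read_labeled_txt(path: str | Path) -> LabeledCloud:
    """Read an annotated cloud from ``x y z r g b label`` rows.

    Space- and tab-delimited rows are accepted and blank lines skipped.
    An optional 8th column is read as the instance id; otherwise instances
    are initialised to -1. Labels outside {0, 1, 2} raise :class:`ParseError`
    with the offending line number.
    """
    coords, colors, semantic, instance = [], [], [], []
    with open(path, "r") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) < 7:
                raise ParseError(
                    f"expected >= 7 fields 'x y z r g b label', got {len(parts)}",
                    lineno,
                )
            try:
                xyz = [float(v) for v in parts[:3]]
                rgb = [int(round(float(v))) for v in parts[3:6]]
                label = int(round(float(parts[6])))
                inst = int(round(float(parts[7]))) if len(parts) >= 8 else NOISE_INSTANCE
            except ValueError as exc:
                raise ParseError(f"non-numeric field ({exc})", lineno) from None
            if label not in (0, 1, 2):
                raise ParseError(f"semantic label {label} outside {{0,1,2}}", lineno)
            coords.append(xyz)
            colors.append(rgb)
            semantic.append(label)
            instance.append(inst)
    cloud = PointCloud(
        np.asarray(coords, dtype=np.float64).reshape(-1, 3),
        np.asarray(colors, dtype=np.uint8).reshape(-1, 3) if colors else None,
    )
    return LabeledCloud(cloud, np.asarray(semantic, dtype=np.int64),
                        np.asarray(instance, dtype=np.int64))


def write_labeled_txt(
    labeled: LabeledCloud, path: str | Path, include_instance: bool = False
) -> None:
    """Write ``x y z r g b label`` rows (plus instance as 8th column if asked)."""
    cloud = labeled.cloud
    colors = (
        cloud.colors
        if cloud.has_colors
        else np.zeros((len(cloud), 3), dtype=np.uint8)
    )
    with open(path, "w") as fh:
        for i in range(len(cloud)):
            x, y, z = cloud.coords[i]
            r, g, b = colors[i]
            row = f"{x:.17g} {y:.17g} {z:.17g} {r} {g} {b} {labeled.semantic[i]}"
            if include_instance:
                row += f" {labeled.instance[i]}"
            fh.write(row + "\n")


_REPORT_HEADER = [
    "kind",
    "instance",
    "plant_height_cm",
    "stem_diameter_mm",
    "leaf_length_cm",
    "leaf_width_cm",
    "leaf_angle_deg",
    "leaf_area_cm2",
]


def write_trait_report(report: TraitReport, path: str | Path) -> None:
    """Write the trait report as CSV: one plant row, one row per leaf.

    Units are recorded in the column names (cm, mm, degrees, cm^2).
    """
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_REPORT_HEADER)
        writer.writerow(
            ["plant", "", f"{report.plant_height_cm:.6g}",
             f"{report.stem_diameter_mm:.6g}", "", "", "", ""]
        )
        for leaf in report.leaves:
            writer.writerow(
                ["leaf", leaf.instance_id, "", "",
                 f"{leaf.length_cm:.6g}", f"{leaf.width_cm:.6g}",
                 f"{leaf.angle_deg:.6g}", f"{leaf.area_cm2:.6g}"]
            )


def read_trait_report(path: str | Path) -> TraitReport:
    """Parse a CSV written by :func:`write_trait_report`."""
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if not rows or rows[0] != _REPORT_HEADER:
        raise FormatError("unrecognised trait report header")
    plant = next((r for r in rows[1:] if r and r[0] == "plant"), None)
    if plant is None:
        raise FormatError("trait report has no plant row")
    leaves = [
        LeafTraits(int(r[1]), float(r[4]), float(r[5]), float(r[6]), float(r[7]))
        for r in rows[1:]
        if r and r[0] == "leaf"
    ]
    return TraitReport(float(plant[2]), float(plant[3]), leaves)
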