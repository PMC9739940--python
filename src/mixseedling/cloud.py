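"""Point-cloud data model and readers/writers.

The pipeline's universal currency is the :class:`LabeledCloud`: an ``N x 3``
coordinate array with optional per-point semantic labels (0 = stem, 1 = leaf,
-1 = unlabeled sentinel), instance ids, a noise mask (synthetic data only) and
unit normals.  Supported on-disk formats are PLY (ascii and
binary_little_endian), PCD v0.7 (ascii and binary) and whitespace-separated
XYZ with optional label columns.  Coordinates are stored as 64-bit floats in
the binary formats so a write -> read round trip is bit-identical.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np

__all__ = ["Frame", "LabeledCloud", "Plane", "read_cloud", "write_cloud"]


class Frame(enum.Enum):
    """Coordinate frame: raw sensor meters, or unit-normalized."""

    SENSOR = "sensor"
    NORMALIZED = "normalized"


class CloudValidationError(ValueError):
    """A cloud violates a structural invariant (non-finite row, length mismatch...)."""


@dataclass
class LabeledCloud:
    """``N x 3`` point coordinates with optional per-point annotations.

    Parameters
    ----------
    points:
        ``(N, 3)`` float coordinates; must be finite, ``N >= 1``.
    semantic:
        Optional ``(N,)`` integer organ class: 0 = stem, 1 = leaf,
        -1 = unlabeled sentinel (excluded from losses and metrics).
    instance:
        Optional ``(N,)`` integer instance id ``>= 0`` (stem is instance 0);
        -1 marks unlabeled points.
    noise_mask:
        Optional ``(N,)`` boolean, true for points injected by the synthetic
        sensor-noise model.
    normals:
        Optional ``(N, 3)`` unit vectors.
    frame:
        Which coordinate frame the points live in.
    """

    points: np.ndarray
    semantic: Optional[np.ndarray] = None
    instance: Optional[np.ndarray] = None
    noise_mask: Optional[np.ndarray] = None
    normals: Optional[np.ndarray] = None
    frame: Frame = Frame.SENSOR
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise CloudValidationError(f"points must be (N, 3), got {self.points.shape}")
        if len(self.points) < 1:
            raise CloudValidationError("cloud must contain at least one point")
        bad = ~np.isfinite(self.points).all(axis=1)
        if bad.any():
            raise CloudValidationError(f"non-finite coordinate at row {int(np.flatnonzero(bad)[0])}")
        n = len(self.points)
        for name in ("semantic", "instance"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=np.int64)
                if arr.shape != (n,):
                    raise CloudValidationError(f"{name} must have length {n}, got {arr.shape}")
                setattr(self, name, arr)
        if self.noise_mask is not None:
            self.noise_mask = np.asarray(self.noise_mask, dtype=bool)
            if self.noise_mask.shape != (n,):
                raise CloudValidationError(f"noise_mask must have length {n}")
        if self.normals is not None:
            self.normals = np.asarray(self.normals, dtype=np.float64)
            if self.normals.shape != (n, 3):
                raise CloudValidationError(f"normals must be ({n}, 3)")
            norms = np.linalg.norm(self.normals, axis=1)
            if not np.allclose(norms, 1.0, atol=1e-6):
                raise CloudValidationError("normals must have unit length within 1e-6")

    def __len__(self) -> int:
        return len(self.points)

    def select(self, index) -> "LabeledCloud":
        """Subset or reorder by an index/mask array, carrying every attribute."""
        return LabeledCloud(
            points=self.points[index],
            semantic=None if self.semantic is None else self.semantic[index],
            instance=None if self.instance is None else self.instance[index],
            noise_mask=None if self.noise_mask is None else self.noise_mask[index],
            normals=None if self.normals is None else self.normals[index],
            frame=self.frame,
            metadata=dict(self.metadata),
        )

    def with_(self, **changes) -> "LabeledCloud":
        return replace(self, **changes)


@dataclass(frozen=True)
class Plane:
    """Plane ``normal . x + offset = 0`` with a unit normal."""

    normal: np.ndarray
    offset: float

    def __post_init__(self) -> None:
        n = np.asarray(self.normal, dtype=np.float64)
        if n.shape != (3,) or abs(np.linalg.norm(n) - 1.0) > 1e-9:
            raise ValueError("plane normal must be a unit 3-vector (within 1e-9)")
        object.__setattr__(self, "normal", n)
        object.__setattr__(self, "offset", float(self.offset))

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=np.float64) @ self.normal + self.offset


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_FORMATS = ("ply", "pcd", "xyz")

# per-attribute (ply type, numpy dtype) used on write
_PLY_ATTRS = [
    ("semantic", "int", "<i4"),
    ("instance", "int", "<i4"),
    ("noise_mask", "uchar", "<u1"),
]
_PLY_TYPE_TO_DTYPE = {
    "char": "<i1", "uchar": "<u1", "int8": "<i1", "uint8": "<u1",
    "short": "<i2", "ushort": "<u2", "int16": "<i2", "uint16": "<u2",
    "int": "<i4", "uint": "<u4", "int32": "<i4", "uint32": "<u4",
    "float": "<f4", "float32": "<f4", "double": "<f8", "float64": "<f8",
}


def _infer_format(path: Path, format: Optional[str]) -> str:
    if format is not None:
        fmt = format.lower()
    else:
        fmt = path.suffix.lstrip(".").lower()
        if fmt == "txt":
            fmt = "xyz"
    if fmt not in _FORMATS:
        raise ValueError(f"unsupported point-cloud format {fmt!r}; expected one of {_FORMATS}")
    return fmt


def read_cloud(path, format: Optional[str] = None) -> LabeledCloud:
    """Read a point cloud from PLY, PCD or ASCII XYZ.

    Point order is preserved exactly as stored.  Per-point integer attributes
    named ``semantic`` and ``instance`` populate the corresponding label
    arrays; ``noise_mask`` populates the boolean mask.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    fmt = _infer_format(path, format)
    if fmt == "ply":
        return _read_ply(path)
    if fmt == "pcd":
        return _read_pcd(path)
    return _read_xyz(path)


def write_cloud(cloud: LabeledCloud, path, format: Optional[str] = None, binary: bool = True) -> None:
    """Write a cloud; see :func:`read_cloud` for the attribute conventions.

    XYZ cannot carry the noise mask or normals; writing a cloud with either to
    XYZ raises rather than silently dropping them.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "ply":
        _write_ply(cloud, path, binary=binary)
    elif fmt == "pcd":
        _write_pcd(cloud, path, binary=binary)
    else:
        if cloud.noise_mask is not None or cloud.normals is not None:
            raise ValueError("XYZ format cannot store noise_mask/normals; use PLY or PCD")
        _write_xyz(cloud, path)


# -- PLY --------------------------------------------------------------------

def _read_ply(path: Path) -> LabeledCloud:
    with open(path, "rb") as fh:
        magic = fh.readline().strip()
        if magic != b"ply":
            raise IOError(f"{path}: not a PLY file")
        fmt_line = None
        props: list[tuple[str, str]] = []  # (type, name) of the vertex element
        n_vertex = None
        in_vertex = False
        while True:
            line = fh.readline()
            if not line:
                raise IOError(f"{path}: unexpected EOF in PLY header")
            tokens = line.decode("ascii").strip().split()
            if not tokens or tokens[0] == "comment":
                continue
            if tokens[0] == "format":
                fmt_line = tokens[1]
            elif tokens[0] == "element":
                in_vertex = tokens[1] == "vertex"
                if in_vertex:
                    n_vertex = int(tokens[2])
            elif tokens[0] == "property" and in_vertex:
                if tokens[1] == "list":
                    raise IOError(f"{path}: list properties on vertices are not supported")
                props.append((tokens[1], tokens[2]))
            elif tokens[0] == "end_header":
                break
        if n_vertex is None:
            raise IOError(f"{path}: PLY file has no vertex element")
        if fmt_line not in ("ascii", "binary_little_endian"):
            raise IOError(f"{path}: unsupported PLY format {fmt_line!r}")
        dtype = np.dtype([(name, _PLY_TYPE_TO_DTYPE[typ]) for typ, name in props])
        if fmt_line == "ascii":
            rows = []
            for _ in range(n_vertex):
                rows.append(tuple(fh.readline().split()))
            rec = np.array(rows, dtype=dtype)
        else:
            rec = np.frombuffer(fh.read(dtype.itemsize * n_vertex), dtype=dtype, count=n_vertex)
    return _cloud_from_record(rec, path)


def _cloud_from_record(rec: np.ndarray, path: Path) -> LabeledCloud:
    names = rec.dtype.names
    for coord in ("x", "y", "z"):
        if coord not in names:
            raise IOError(f"{path}: missing vertex coordinate {coord!r}")
    pts = np.stack([rec["x"], rec["y"], rec["z"]], axis=1).astype(np.float64)
    bad = ~np.isfinite(pts).all(axis=1)
    if bad.any():
        raise CloudValidationError(f"{path}: non-finite coordinate at row {int(np.flatnonzero(bad)[0])}")
    kw = {}
    if "semantic" in names:
        kw["semantic"] = rec["semantic"].astype(np.int64)
    if "instance" in names:
        kw["instance"] = rec["instance"].astype(np.int64)
    if "noise_mask" in names:
        kw["noise_mask"] = rec["noise_mask"].astype(bool)
    if all(f"n{c}" in names for c in "xyz"):
        kw["normals"] = np.stack([rec["nx"], rec["ny"], rec["nz"]], axis=1).astype(np.float64)
    return LabeledCloud(points=pts, **kw)


def _vertex_record(cloud: LabeledCloud) -> tuple[np.ndarray, list[tuple[str, str]]]:
    fields: list[tuple[str, str, str]] = [("x", "double", "<f8"), ("y", "double", "<f8"), ("z", "double", "<f8")]
    if cloud.normals is not None:
        fields += [(f"n{c}", "double", "<f8") for c in "xyz"]
    for name, ply_t, np_t in _PLY_ATTRS:
        if getattr(cloud, name) is not None:
            fields.append((name, ply_t, np_t))
    rec = np.empty(len(cloud), dtype=np.dtype([(n, t) for n, _, t in fields]))
    rec["x"], rec["y"], rec["z"] = cloud.points.T
    if cloud.normals is not None:
        rec["nx"], rec["ny"], rec["nz"] = cloud.normals.T
    for name, _, _ in _PLY_ATTRS:
        arr = getattr(cloud, name)
        if arr is not None:
            rec[name] = arr
    return rec, [(n, p) for n, p, _ in fields]


def _write_ply(cloud: LabeledCloud, path: Path, binary: bool) -> None:
    rec, fields = _vertex_record(cloud)
    header = ["ply", f"format {'binary_little_endian' if binary else 'ascii'} 1.0",
              f"element vertex {len(rec)}"]
    header += [f"property {ply_t} {name}" for name, ply_t in fields]
    header.append("end_header")
    with open(path, "wb") as fh:
        fh.write(("\n".join(header) + "\n").encode("ascii"))
        if binary:
            fh.write(rec.tobytes())
        else:
            for row in rec:
                fh.write((" ".join(_fmt_ascii(v) for v in row) + "\n").encode("ascii"))


def _fmt_ascii(v) -> str:
    if np.issubdtype(np.asarray(v).dtype, np.floating):
        return format(float(v), ".9g")
    return str(int(v))


# -- PCD --------------------------------------------------------------------

_PCD_TYPE = {"<f8": ("F", 8), "<f4": ("F", 4), "<i4": ("I", 4), "<u1": ("U", 1)}
_PCD_DTYPE = {("F", 8): "<f8", ("F", 4): "<f4", ("I", 4): "<i4", ("I", 8): "<i8",
              ("I", 2): "<i2", ("I", 1): "<i1", ("U", 1): "<u1", ("U", 2): "<u2",
              ("U", 4): "<u4"}


def _read_pcd(path: Path) -> LabeledCloud:
    with open(path, "rb") as fh:
        header: dict[str, list[str]] = {}
        while True:
            line = fh.readline()
            if not line:
                raise IOError(f"{path}: unexpected EOF in PCD header")
            text = line.decode("ascii").strip()
            if text.startswith("#") or not text:
                continue
            key, *vals = text.split()
            header[key] = vals
            if key == "DATA":
                break
        try:
            names = header["FIELDS"]
            sizes = [int(s) for s in header["SIZE"]]
            types = header["TYPE"]
            n = int(header["POINTS"][0])
            mode = header["DATA"][0]
        except KeyError as exc:
            raise IOError(f"{path}: malformed PCD header, missing {exc}") from exc
        dtype = np.dtype([(nm, _PCD_DTYPE[(t, s)]) for nm, t, s in zip(names, types, sizes)])
        if mode == "ascii":
            rows = [tuple(fh.readline().split()) for _ in range(n)]
            rec = np.array(rows, dtype=dtype)
        elif mode == "binary":
            rec = np.frombuffer(fh.read(dtype.itemsize * n), dtype=dtype, count=n)
        else:
            raise IOError(f"{path}: unsupported PCD DATA mode {mode!r}")
    return _cloud_from_record(rec, path)


def _write_pcd(cloud: LabeledCloud, path: Path, binary: bool) -> None:
    rec, _ = _vertex_record(cloud)
    names = rec.dtype.names
    sizes, types = [], []
    for nm in names:
        t, s = _PCD_TYPE[rec.dtype[nm].str.replace("=", "<").replace(">", "<").replace("|", "<")]
        types.append(t)
        sizes.append(s)
    n = len(rec)
    header = "\n".join([
        "# .PCD v0.7 - Point Cloud Data file format",
        "VERSION 0.7",
        "FIELDS " + " ".join(names),
        "SIZE " + " ".join(map(str, sizes)),
        "TYPE " + " ".join(types),
        "COUNT " + " ".join(["1"] * len(names)),
        f"WIDTH {n}",
        "HEIGHT 1",
        "VIEWPOINT 0 0 0 1 0 0 0",
        f"POINTS {n}",
        f"DATA {'binary' if binary else 'ascii'}",
    ]) + "\n"
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        if binary:
            fh.write(rec.tobytes())
        else:
            for row in rec:
                fh.write((" ".join(_fmt_ascii(v) for v in row) + "\n").encode("ascii"))


# -- XYZ --------------------------------------------------------------------

def _read_xyz(path: Path) -> LabeledCloud:
    data = np.loadtxt(path, ndmin=2)
    if data.shape[1] not in (3, 5):
        raise IOError(f"{path}: XYZ file must have 3 or 5 columns, got {data.shape[1]}")
    pts = data[:, :3]
    bad = ~np.isfinite(pts).all(axis=1)
    if bad.any():
        raise CloudValidationError(f"{path}: non-finite coordinate at row {int(np.flatnonzero(bad)[0])}")
    kw = {}
    if data.shape[1] == 5:
        kw["semantic"] = data[:, 3].astype(np.int64)
        kw["instance"] = data[:, 4].astype(np.int64)
    return LabeledCloud(points=pts, **kw)


def _write_xyz(cloud: LabeledCloud, path: Path) -> None:
    with open(path, "w") as fh:
        has_labels = cloud.semantic is not None or cloud.instance is not None
        sem = cloud.semantic if cloud.semantic is not None else np.full(len(cloud), -1)
        ins = cloud.instance if cloud.instance is not None else np.full(len(cloud), -1)
        for i, (x, y, z) in enumerate(cloud.points):
            row = f"{x:.9g} {y:.9g} {z:.9g}"
            if has_labels:
                row += f" {sem[i]} {ins[i]}"
            fh.write(row + "\n")
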