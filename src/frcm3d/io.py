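"""Volume readers and writers: raw container, binvox, NIfTI.

The raw container is a small self-describing format used for exact
round trips: an ASCII header (magic line, dims, dtype) followed by a
little-endian row-major float payload.

binvox follows the public run-length spec (pairs of value/count bytes,
y fastest, then z, then x).  NIfTI goes through nibabel with the scaling
slope/intercept applied.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np

from .moments import VoxelGrid

__all__ = ["read_volume", "write_volume", "read_raw", "write_raw",
           "read_binvox", "write_binvox", "read_nifti", "write_nifti",
           "write_descriptors", "read_descriptors", "ParseError"]

_RAW_MAGIC = b"#frcm-raw 1\n"


class ParseError(ValueError):
    """A volume file could not be parsed; carries the failing byte offset."""

    def __init__(self, message: str, offset: int | None = None):
        if offset is not None:
            message = f"{message} (byte offset {offset})"
        super().__init__(message)
        self.offset = offset


def write_raw(path, volume) -> None:
    vol = VoxelGrid.coerce(volume)
    data = np.ascontiguousarray(vol.data, dtype="<f8")
    with open(path, "wb") as f:
        f.write(_RAW_MAGIC)
        f.write(("dims %d %d %d\n" % vol.dims).encode())
        f.write(b"dtype float64-le\n")
        f.write(b"data\n")
        f.write(data.tobytes())


def read_raw(path) -> VoxelGrid:
    with open(path, "rb") as f:
        magic = f.readline()
        if magic != _RAW_MAGIC:
            raise ParseError(f"bad magic line {magic!r} in {path}", 0)
        dims_line = f.readline().decode(errors="replace").split()
        if len(dims_line) != 4 or dims_line[0] != "dims":
            raise ParseError(f"bad dims line in {path}", len(magic))
        dims = tuple(int(v) for v in dims_line[1:])
        if min(dims) < 1:
            raise ParseError(f"unsupported dims {dims}", len(magic))
        f.readline()  # dtype
        f.readline()  # data
        offset = f.tell()
        payload = f.read()
    expected = dims[0] * dims[1] * dims[2] * 8
    if len(payload) != expected:
        raise ParseError(
            f"truncated payload: got {len(payload)} of {expected} bytes", offset
        )
    return VoxelGrid(np.frombuffer(payload, dtype="<f8").reshape(dims).copy())


def write_binvox(path, volume, threshold: float = 0.5) -> None:
    """Occupancy (data > threshold) in run-length binvox encoding."""
    vol = VoxelGrid.coerce(volume)
    if len(set(vol.dims)) != 1:
        raise ValueError("binvox requires a cubic grid")
    occ = (np.transpose(vol.data, (0, 2, 1)).ravel() > threshold).astype(np.uint8)
    with open(path, "wb") as f:
        f.write(b"#binvox 1\n")
        f.write(("dim %d %d %d\n" % vol.dims).encode())
        f.write(b"translate 0 0 0\n")
        f.write(b"scale 1\n")
        f.write(b"data\n")
        i = 0
        while i < occ.size:
            v = occ[i]
            run = 1
            while i + run < occ.size and occ[i + run] == v and run < 255:
                run += 1
            f.write(bytes([int(v), run]))
            i += run


def read_binvox(path) -> VoxelGrid:
    with open(path, "rb") as f:
        line = f.readline()
        if not line.startswith(b"#binvox"):
            raise ParseError(f"not a binvox file: {line!r}", 0)
        dims = None
        while True:
            offset = f.tell()
            line = f.readline()
            if not line:
                raise ParseError("header ended before 'data'", offset)
            if line.startswith(b"dim"):
                dims = tuple(int(v) for v in line.split()[1:4])
            elif line.startswith(b"data"):
                break
        if dims is None or min(dims) < 1:
            raise ParseError(f"missing or invalid dim line ({dims})", offset)
        payload = f.read()
    total = dims[0] * dims[1] * dims[2]
    if len(payload) % 2 != 0:
        raise ParseError("odd run-length payload size", offset)
    pairs = np.frombuffer(payload, dtype=np.uint8).reshape(-1, 2)
    flat = np.repeat(pairs[:, 0], pairs[:, 1]).astype(float)
    if flat.size != total:
        raise ParseError(
            f"run lengths decode to {flat.size} voxels, expected {total}", offset
        )
    # stored order: y fastest, then z, then x
    data = flat.reshape(dims[0], dims[2], dims[1]).transpose(0, 2, 1)
    return VoxelGrid(data)


def read_nifti(path) -> VoxelGrid:
    import nibabel as nib

    try:
        img = nib.load(path)
    except Exception as exc:  # nibabel raises several types
        raise ParseError(f"cannot parse NIfTI file {path}: {exc}") from exc
    data = np.asarray(img.get_fdata(), dtype=float)
    if data.ndim != 3:
        raise ParseError(f"expected a 3D NIfTI volume, got ndim={data.ndim}")
    return VoxelGrid(data)


def write_nifti(path, volume) -> None:
    import nibabel as nib

    vol = VoxelGrid.coerce(volume)
    nib.save(nib.Nifti1Image(vol.data, np.eye(4)), path)


_READERS = {"raw": read_raw, "binvox": read_binvox, "nifti": read_nifti}
_WRITERS = {"raw": write_raw, "binvox": write_binvox, "nifti": write_nifti}


def _infer_format(path) -> str:
    name = str(path).lower()
    if name.endswith(".binvox"):
        return "binvox"
    if name.endswith((".nii", ".nii.gz")):
        return "nifti"
    return "raw"


def read_volume(path, format: str | None = None) -> VoxelGrid:
    if not os.path.exists(path):
        raise ParseError(f"no such file: {path}")
    fmt = format or _infer_format(path)
    if fmt not in _READERS:
        raise ValueError(f"unknown format {fmt!r}")
    return _READERS[fmt](path)


def write_volume(path, volume, format: str | None = None) -> None:
    fmt = format or _infer_format(path)
    if fmt not in _WRITERS:
        raise ValueError(f"unknown format {fmt!r}")
    _WRITERS[fmt](path, volume)


def write_descriptors(path, rows: np.ndarray, r_max: int, alphas,
                      labels=None) -> None:
    """One descriptor per row, TSV, header names the (n, m, p) triples."""
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    n1 = r_max + 1
    if rows.shape[1] != n1**3:
        raise ValueError(f"descriptor width {rows.shape[1]} != {n1 ** 3}")
    header = ["label"] if labels is not None else []
    header += [f"frcmi_{n}_{m}_{p}" for n in range(n1) for m in range(n1) for p in range(n1)]
    path = Path(path)
    with open(path, "w") as f:
        f.write("# alphas = %s; r_max = %d\n" % (list(map(float, alphas)), r_max))
        f.write("\t".join(header) + "\n")
        for i, row in enumerate(rows):
            cells = [str(int(labels[i]))] if labels is not None else []
            cells += [f"{v:.12g}" for v in row]
            f.write("\t".join(cells) + "\n")


def read_descriptors(path):
    """Returns (rows, labels-or-None)."""
    with open(path) as f:
        f.readline()  # metadata comment
        header = f.readline().rstrip("\n").split("\t")
        has_labels = header and header[0] == "label"
        rows, labels = [], []
        for line in f:
            cells = line.rstrip("\n").split("\t")
            if has_labels:
                labels.append(int(cells[0]))
                cells = cells[1:]
            rows.append([float(v) for v in cells])
    return np.array(rows), (np.array(labels) if has_labels else None)
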