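"""Reading and writing volumes: NRRD files and 2D slice stacks.

NRRD (Nearly Raw Raster Data) is the toolkit's standard on-disk format: a
short text header followed by the voxel payload, optionally compressed. This
module implements the format directly — attached (.nrrd) and detached (.nhdr)
headers; raw, gzip and bzip2 encodings — because the toolkit needs explicit
control over the bzip2 option used to shrink uploads, and the format is small
enough to own.

Conventions
-----------
* In memory, arrays are indexed ``(z, y, x)`` (slice, row, column).
* On disk, NRRD ``sizes`` run fast-to-slow ``(x, y, z)``; a C-ordered
  ``(z, y, x)`` array already has x fastest, so the payload bytes need no
  transposition — only the header axis order is reversed.
* Payloads are little-endian always; big-endian files are byte-swapped on read.
* Slice stacks are ordered by natural-numeric filename sort, so ``s2.tif``
  precedes ``s10.tif`` regardless of directory listing order.
"""

from __future__ import annotations

import bz2
import gzip
import os
import re
import zlib
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .errors import (
    CorruptFileError,
    DimensionMismatchError,
    NoInputError,
    UnsupportedDtypeError,
    UnsupportedEncodingError,
)
from .types import SUPPORTED_DTYPES, Volume3D

_SLICE_EXTENSIONS = {".tif", ".tiff", ".bmp", ".jpg", ".jpeg", ".png"}

# NRRD type strings we emit (canonical) and accept (synonyms).
_NRRD_TYPE_FOR_TAG = {"uint8": "unsigned char", "uint16": "unsigned short",
                      "float32": "float"}
_TAG_FOR_NRRD_TYPE = {
    "unsigned char": "uint8", "uchar": "uint8", "uint8": "uint8",
    "uint8_t": "uint8",
    "unsigned short": "uint16", "ushort": "uint16", "uint16": "uint16",
    "uint16_t": "uint16", "unsigned short int": "uint16",
    "float": "float32", "float32": "float32",
}

_ENCODINGS = {"raw", "gzip", "gz", "bzip2", "bz2"}


# ---------------------------------------------------------------------------
# slice stacks
# ---------------------------------------------------------------------------

def natural_sort_key(name: str) -> tuple:
    """Sort key treating digit runs as numbers: s2 < s10, slice_9 < slice_11."""
    parts = re.split(r"(\d+)", name)
    return tuple(int(p) if p.isdigit() else p.lower() for p in parts)


@dataclass
class SliceStack:
    """An ordered stack of 2D grey-scale slice files of equal size."""

    directory: Path
    file_list: list[Path]
    bit_depth: int

    @classmethod
    def from_directory(cls, directory: str | os.PathLike) -> "SliceStack":
        directory = Path(directory)
        files = [p for p in directory.iterdir()
                 if p.suffix.lower() in _SLICE_EXTENSIONS]
        if not files:
            raise NoInputError(f"no slice images found in {directory}")
        files.sort(key=lambda p: natural_sort_key(p.name))
        first = _read_slice(files[0])
        bit_depth = first.dtype.itemsize * 8
        return cls(directory=directory, file_list=files, bit_depth=bit_depth)


def _read_slice(path: Path) -> np.ndarray:
    if path.suffix.lower() in {".tif", ".tiff"}:
        img = tifffile.imread(path)
    else:
        img = iio.imread(path)
    img = np.asarray(img)
    if img.ndim != 2:
        raise DimensionMismatchError(
            f"{path.name}: expected a 2D grey image, got shape {img.shape}; "
            "colour slices are rejected (the pipeline is grey-scale only)"
        )
    if img.dtype not in (np.dtype(np.uint8), np.dtype(np.uint16)):
        raise UnsupportedDtypeError(
            f"{path.name}: slice dtype {img.dtype} unsupported (8/16-bit grey only)"
        )
    return img


def read_slice_stack(
    stack: SliceStack | str | os.PathLike,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> Volume3D:
    """Assemble a stack of 2D slices into a Volume3D, slice k at data[k].

    ``stack`` may be a :class:`SliceStack` or a directory path. All slices
    must share dimensions and bit depth; a mismatch raises
    :class:`DimensionMismatchError` naming the offending file.
    """
    if not isinstance(stack, SliceStack):
        stack = SliceStack.from_directory(stack)
    first = _read_slice(stack.file_list[0])
    data = np.empty((len(stack.file_list),) + first.shape, dtype=first.dtype)
    data[0] = first
    for k, path in enumerate(stack.file_list[1:], start=1):
        img = _read_slice(path)
        if img.shape != first.shape or img.dtype != first.dtype:
            raise DimensionMismatchError(
                f"{path.name}: shape {img.shape} dtype {img.dtype} differs from "
                f"first slice {stack.file_list[0].name} "
                f"(shape {first.shape} dtype {first.dtype})"
            )
        data[k] = img
    return Volume3D(data, spacing, {"source": str(stack.directory)})


def write_slice_stack(
    vol: Volume3D, directory: str | os.PathLike, prefix: str = "slice",
    ext: str = ".tif",
) -> list[Path]:
    """Write each z-slice as a 2D image file; inverse of read_slice_stack."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if vol.dtype_tag == "float32":
        raise UnsupportedDtypeError("slice stacks are 8/16-bit integer only")
    paths = []
    width = len(str(vol.shape[0] - 1))
    for k in range(vol.shape[0]):
        path = directory / f"{prefix}{k:0{width}d}{ext}"
        if ext.lower() in {".tif", ".tiff"}:
            tifffile.imwrite(path, vol.data[k])
        else:
            iio.imwrite(path, vol.data[k])
        paths.append(path)
    return paths


# ---------------------------------------------------------------------------
# NRRD, low level
# ---------------------------------------------------------------------------

_RESERVED_FIELDS = {
    "type", "dimension", "sizes", "spacings", "encoding", "endian",
    "data file", "datafile", "kinds", "space directions", "space",
    "space origin", "content",
}


def _encode_payload(raw: bytes, encoding: str) -> bytes:
    if encoding == "raw":
        return raw
    if encoding == "gzip":
        return gzip.compress(raw, mtime=0)
    if encoding == "bzip2":
        return bz2.compress(raw)
    raise UnsupportedEncodingError(f"unsupported NRRD encoding {encoding!r}")


def _decode_payload(blob: bytes, encoding: str, expected: int, path: Path) -> bytes:
    try:
        if encoding == "raw":
            raw = blob
        elif encoding in ("gzip", "gz"):
            # tolerate trailing garbage the way teem does
            raw = zlib.decompressobj(wbits=47).decompress(blob)
        elif encoding in ("bzip2", "bz2"):
            raw = bz2.decompress(blob)
        else:
            raise UnsupportedEncodingError(
                f"{path}: unsupported NRRD encoding {encoding!r}")
    except (OSError, EOFError, zlib.error, ValueError) as exc:
        raise CorruptFileError(f"{path}: payload failed to decompress: {exc}") from exc
    if len(raw) < expected:
        raise CorruptFileError(
            f"{path}: truncated payload ({len(raw)} bytes, expected {expected})")
    return raw[:expected]


def write_nrrd_array(
    path: str | os.PathLike,
    array: np.ndarray,
    spacings: tuple[float, ...],
    metadata: dict[str, str] | None = None,
    encoding: str = "raw",
    detached: bool = False,
    kinds: tuple[str, ...] | None = None,
) -> Path:
    """Write an n-D array as NRRD; sizes/spacings emitted fast-to-slow.

    ``spacings`` are given slow-to-fast (matching the array's index order);
    NaN entries (e.g. a vector component axis) are written as ``nan``.
    """
    path = Path(path)
    if encoding not in ("raw", "gzip", "bzip2"):
        raise UnsupportedEncodingError(f"unsupported NRRD encoding {encoding!r}")
    array = np.ascontiguousarray(array)
    if array.dtype.newbyteorder("<") != array.dtype and array.dtype.byteorder == ">":
        array = array.astype(array.dtype.newbyteorder("<"))
    tag = {np.dtype(v): k for k, v in SUPPORTED_DTYPES.items()}.get(array.dtype)
    if tag is None:
        raise UnsupportedDtypeError(f"cannot write dtype {array.dtype} to NRRD")

    lines = ["NRRD0004", "# written by embryotk"]
    lines.append(f"type: {_NRRD_TYPE_FOR_TAG[tag]}")
    lines.append(f"dimension: {array.ndim}")
    lines.append("sizes: " + " ".join(str(n) for n in array.shape[::-1]))
    sp = " ".join("nan" if np.isnan(s) else repr(float(s))
                  for s in spacings[::-1])
    lines.append(f"spacings: {sp}")
    if kinds is not None:
        lines.append("kinds: " + " ".join(kinds[::-1]))
    lines.append(f"encoding: {encoding}")
    lines.append("endian: little")

    data_path = path
    if detached:
        data_name = path.with_suffix("").name + {
            "raw": ".raw", "gzip": ".raw.gz", "bzip2": ".raw.bz2"}[encoding]
        data_path = path.parent / data_name
        lines.append(f"data file: {data_name}")
    for key, value in (metadata or {}).items():
        key = str(key)
        if key.lower() in _RESERVED_FIELDS or ":=" in key:
            raise ValueError(f"metadata key {key!r} clashes with an NRRD field")
        value = str(value).replace("\n", " ")
        lines.append(f"{key}:={value}")

    header = ("\n".join(lines) + "\n").encode("ascii", errors="replace")
    payload = _encode_payload(array.tobytes(order="C"), encoding)
    path.parent.mkdir(parents=True, exist_ok=True)
    if detached:
        path.write_bytes(header)
        data_path.write_bytes(payload)
    else:
        path.write_bytes(header + b"\n" + payload)
    return path


def read_nrrd_array(path: str | os.PathLike):
    """Read an NRRD file -> (array, spacings slow-to-fast, metadata, fields).

    Accepts attached and detached headers and raw/gzip/bzip2 encodings.
    """
    path = Path(path)
    blob = path.read_bytes()
    if not blob.startswith(b"NRRD"):
        raise CorruptFileError(f"{path}: not an NRRD file (magic missing)")

    # header is ASCII lines up to a blank line (attached) or EOF (detached)
    end = blob.find(b"\n\n")
    if end == -1:
        header_bytes, payload = blob, b""
        attached = False
    else:
        header_bytes, payload = blob[:end], blob[end + 2:]
        attached = True

    fields: dict[str, str] = {}
    metadata: dict[str, str] = {}
    for line in header_bytes.decode("ascii", errors="replace").splitlines()[1:]:
        line = line.rstrip("\r")
        if not line or line.startswith("#"):
            continue
        if ":=" in line:
            key, _, value = line.partition(":=")
            metadata[key.strip()] = value.strip()
        elif ": " in line or line.endswith(":"):
            key, _, value = line.partition(":")
            fields[key.strip().lower()] = value.strip()
        else:
            raise CorruptFileError(f"{path}: malformed header line {line!r}")

    for required in ("type", "dimension", "sizes", "encoding"):
        if required not in fields:
            raise CorruptFileError(f"{path}: header missing field {required!r}")

    type_str = fields["type"].lower()
    if type_str not in _TAG_FOR_NRRD_TYPE:
        raise UnsupportedDtypeError(f"{path}: unsupported NRRD type {fields['type']!r}")
    tag = _TAG_FOR_NRRD_TYPE[type_str]
    dtype = np.dtype(SUPPORTED_DTYPES[tag])

    ndim = int(fields["dimension"])
    sizes_fast = [int(s) for s in fields["sizes"].split()]
    if len(sizes_fast) != ndim:
        raise CorruptFileError(f"{path}: sizes/dimension mismatch")
    shape = tuple(sizes_fast[::-1])  # slow-to-fast for numpy

    if "spacings" in fields:
        spacings_fast = [float(s) for s in fields["spacings"].split()]
        spacings = tuple(spacings_fast[::-1])
    elif "space directions" in fields:
        spacings = _spacings_from_directions(fields["space directions"], ndim)
    else:
        spacings = tuple(1.0 for _ in range(ndim))

    encoding = fields["encoding"].lower()
    if encoding not in _ENCODINGS:
        raise UnsupportedEncodingError(
            f"{path}: unsupported NRRD encoding {fields['encoding']!r}")

    datafile = fields.get("data file", fields.get("datafile"))
    if datafile is not None:
        payload = (path.parent / datafile).read_bytes()
    elif not attached:
        raise CorruptFileError(f"{path}: attached header has no payload")

    expected = int(np.prod(shape)) * dtype.itemsize
    raw = _decode_payload(payload, encoding, expected, path)
    array = np.frombuffer(raw, dtype=dtype.newbyteorder("<")).reshape(shape)
    if fields.get("endian", "little").lower() == "big" and dtype.itemsize > 1:
        array = np.frombuffer(raw, dtype=dtype.newbyteorder(">")).reshape(shape)
        array = array.astype(dtype)
    return np.array(array), spacings, metadata, fields


def _spacings_from_directions(text: str, ndim: int) -> tuple[float, ...]:
    # e.g. "(1,0,0) (0,2,0) (0,0,3)" or "none (1,0,0) ..." -> per-axis norms
    vecs = re.findall(r"\(([^)]*)\)|none", text)
    out = []
    for v in vecs:
        if not v:
            out.append(float("nan"))
        else:
            comps = [float(c) for c in v.split(",")]
            out.append(float(np.linalg.norm(comps)))
    while len(out) < ndim:
        out.insert(0, float("nan"))
    return tuple(out[::-1])


# ---------------------------------------------------------------------------
# NRRD, Volume3D level
# ---------------------------------------------------------------------------

def write_nrrd(
    vol: Volume3D,
    path: str | os.PathLike,
    compress: bool = False,
    encoding: str | None = None,
    detached: bool = False,
) -> Path:
    """Write a Volume3D to NRRD.

    By default the payload is raw; ``compress=True`` selects bzip2 (the
    option used to minimise upload bandwidth). ``encoding`` overrides both.
    """
    if encoding is None:
        encoding = "bzip2" if compress else "raw"
    return write_nrrd_array(path, vol.data, vol.spacing,
                            metadata=vol.metadata, encoding=encoding,
                            detached=detached)


def read_nrrd(path: str | os.PathLike) -> Volume3D:
    """Read a 3D NRRD file into a Volume3D (inverse of :func:`write_nrrd`)."""
    array, spacings, metadata, fields = read_nrrd_array(path)
    if array.ndim != 3:
        raise CorruptFileError(
            f"{path}: expected a 3D volume, header says dimension {array.ndim}")
    return Volume3D(array, spacings, metadata)
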