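"""Minimal ENVI cube I/O.

ENVI stores a hyperspectral cube as a flat binary file next to a plain-text
header (``.hdr``) declaring dimensions, data type, interleave and, optionally,
the wavelength list.  Only the features needed by this package are supported:
interleaves BSQ/BIL/BIP, data types 1, 2, 3, 4, 5 and 12, little/big endian.

Cubes are exchanged as ``(bands, rows, cols)`` arrays throughout the package.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np

#: ENVI "data type" codes -> numpy dtypes.
DTYPE_CODES = {
    1: np.uint8,
    2: np.int16,
    3: np.int32,
    4: np.float32,
    5: np.float64,
    12: np.uint16,
}
_DTYPE_TO_CODE = {np.dtype(v): k for k, v in DTYPE_CODES.items()}


def _header_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".hdr")


def write_envi(
    path: str | Path,
    values: np.ndarray,
    wavelengths: np.ndarray | None = None,
    interleave: str = "bsq",
) -> Path:
    """Write a ``(bands, rows, cols)`` cube as an ENVI binary + header pair.

    Returns the path of the binary file; the header is written alongside it
    with an extra ``.hdr`` suffix.
    """
    values = np.asarray(values)
    if values.ndim == 2:  # single-band image
        values = values[None]
    if values.ndim != 3:
        raise ValueError(f"expected a (bands, rows, cols) array, got shape {values.shape}")
    interleave = interleave.lower()
    if interleave not in ("bsq", "bil", "bip"):
        raise ValueError(f"unsupported interleave {interleave!r}")
    code = _DTYPE_TO_CODE.get(values.dtype)
    if code is None:
        values = values.astype(np.float32)
        code = 4
    bands, rows, cols = values.shape
    if interleave == "bsq":
        ordered = values  # (bands, lines, samples)
    elif interleave == "bil":
        ordered = values.transpose(1, 0, 2)  # (lines, bands, samples)
    else:
        ordered = values.transpose(1, 2, 0)  # (lines, samples, bands)

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.ascontiguousarray(ordered).tofile(path)

    lines = [
        "ENVI",
        "file type = ENVI Standard",
        f"samples = {cols}",
        f"lines = {rows}",
        f"bands = {bands}",
        "header offset = 0",
        f"data type = {code}",
        f"interleave = {interleave}",
        "byte order = 0",
    ]
    if wavelengths is not None:
        wl = ", ".join(f"{w:.4f}" for w in np.asarray(wavelengths, dtype=float))
        lines.append("wavelength units = Nanometers")
        lines.append("wavelength = { " + wl + " }")
    _header_path(path).write_text("\n".join(lines) + "\n")
    return path


def _parse_header(text: str) -> dict:
    # Collapse {...} groups (possibly multi-line) before splitting on lines.
    text = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    fields: dict[str, str] = {}
    for line in text.splitlines():
        if "=" not in line:
            continue
        key, _, value = line.partition("=")
        fields[key.strip().lower()] = value.strip()
    return fields


def read_envi(path: str | Path) -> tuple[np.ndarray, np.ndarray | None]:
    """Read an ENVI cube; returns ``(values (bands, rows, cols), wavelengths)``."""
    path = Path(path)
    hdr = _header_path(path)
    if not hdr.exists():  # also accept "cube.hdr" replacing the suffix
        alt = path.with_suffix(".hdr")
        if alt.exists():
            hdr = alt
        else:
            raise FileNotFoundError(f"ENVI header not found for {path}")
    fields = _parse_header(hdr.read_text())

    cols = int(fields["samples"])
    rows = int(fields["lines"])
    bands = int(fields["bands"])
    code = int(fields.get("data type", 4))
    if code not in DTYPE_CODES:
        raise ValueError(f"unsupported ENVI data type {code}")
    dtype = np.dtype(DTYPE_CODES[code])
    offset = int(fields.get("header offset", 0))
    interleave = fields.get("interleave", "bsq").lower()
    byte_order = int(fields.get("byte order", 0))
    if byte_order == 1:
        dtype = dtype.newbyteorder(">")

    raw = np.fromfile(path, dtype=dtype, count=bands * rows * cols, offset=offset)
    if raw.size != bands * rows * cols:
        raise ValueError(f"{path}: expected {bands * rows * cols} values, got {raw.size}")
    if interleave == "bsq":
        values = raw.reshape(bands, rows, cols)
    elif interleave == "bil":
        values = raw.reshape(rows, bands, cols).transpose(1, 0, 2)
    elif interleave == "bip":
        values = raw.reshape(rows, cols, bands).transpose(2, 0, 1)
    else:
        raise ValueError(f"unsupported interleave {interleave!r}")
    values = np.ascontiguousarray(values, dtype=dtype.newbyteorder("="))

    wavelengths = None
    if "wavelength" in fields:
        inner = fields["wavelength"].strip().strip("{}").strip()
        if inner:
            wavelengths = np.array([float(tok) for tok in inner.split(",") if tok.strip()])
    return values, wavelengths
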