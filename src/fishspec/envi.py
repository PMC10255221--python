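"""Minimal ENVI-style hypercube I/O (text header + raw binary pair).

Supports BIL, BSQ and BIP interleaves, little/big endian, and the
common numeric data types.  The header carries the wavelength list, the
mode tag and the exposure time so a cube round-trips losslessly.
"""

from __future__ import annotations

import os
import re

import numpy as np

from .containers import Hypercube

_DTYPES = {1: np.uint8, 2: np.int16, 3: np.int32, 4: np.float32,
           5: np.float64, 12: np.uint16, 13: np.uint32}
_DTYPE_CODES = {np.dtype(v): k for k, v in _DTYPES.items()}

# axis order of the flat binary per interleave: (lines, samples, bands) is
# the in-memory convention (rows, cols, bands)
_INTERLEAVE_AXES = {
    "bil": (0, 2, 1),  # line, band, sample
    "bsq": (2, 0, 1),  # band, line, sample
    "bip": (0, 1, 2),  # line, sample, band
}


def _parse_header(text: str) -> dict:
    fields: dict = {}
    # multi-line { ... } values first
    for m in re.finditer(r"(\w[\w ]*?)\s*=\s*\{(.*?)\}", text, re.S):
        key = m.group(1).strip().lower()
        fields[key] = [v.strip() for v in m.group(2).replace("\n", " ").split(",")
                       if v.strip()]
    for line in text.splitlines():
        if "=" in line and "{" not in line:
            key, _, val = line.partition("=")
            fields[key.strip().lower()] = val.strip()
    return fields


def read_envi_cube(path: str) -> Hypercube:
    """Read a ``.hdr`` + binary pair into a :class:`Hypercube`.

    ``path`` may point at either file of the pair.  Errors on a missing
    wavelength list or on a size mismatch between header and binary.
    """
    base = re.sub(r"\.(hdr|img|dat|raw)$", "", path)
    hdr_path = base + ".hdr"
    bin_path = next(
        (base + ext for ext in (".img", ".dat", ".raw", "") if
         os.path.exists(base + ext) and not (base + ext).endswith(".hdr")),
        None,
    )
    if not os.path.exists(hdr_path) or bin_path is None:
        raise FileNotFoundError(f"need header and binary pair for {path!r}")
    with open(hdr_path) as fh:
        fields = _parse_header(fh.read())

    try:
        samples = int(fields["samples"])
        lines = int(fields["lines"])
        bands = int(fields["bands"])
    except KeyError as err:
        raise ValueError(f"ENVI header missing {err} field") from None
    if "wavelength" not in fields:
        raise ValueError("ENVI header missing wavelength list")
    wavelengths = np.array([float(w) for w in fields["wavelength"]])
    if len(wavelengths) != bands:
        raise ValueError(
            f"header declares {bands} bands but lists "
            f"{len(wavelengths)} wavelengths"
        )
    dtype = np.dtype(_DTYPES[int(fields.get("data type", 4))])
    if int(fields.get("byte order", 0)) == 1:
        dtype = dtype.newbyteorder(">")
    interleave = str(fields.get("interleave", "bil")).lower()
    if interleave not in _INTERLEAVE_AXES:
        raise ValueError(f"unsupported interleave {interleave!r}")

    raw = np.fromfile(bin_path, dtype=dtype)
    if raw.size != samples * lines * bands:
        raise ValueError(
            f"binary holds {raw.size} values, header implies "
            f"{samples * lines * bands}"
        )
    ax = _INTERLEAVE_AXES[interleave]
    dims = {0: lines, 1: samples, 2: bands}  # memory axis -> length
    data = np.transpose(raw.reshape(dims[ax[0]], dims[ax[1]], dims[ax[2]]),
                        np.argsort(ax))
    return Hypercube(
        data=np.ascontiguousarray(data.astype(dtype.newbyteorder("="))),
        wavelengths=wavelengths,
        mode=str(fields.get("mode", "FL")),
        exposure_ms=float(fields.get("exposure ms", 300.0)),
    )


def write_envi_cube(cube: Hypercube, path: str,
                    interleave: str = "bil") -> tuple[str, str]:
    """Write a cube as a ``.hdr`` + ``.img`` pair; returns both paths."""
    if interleave not in _INTERLEAVE_AXES:
        raise ValueError(f"unsupported interleave {interleave!r}")
    base = re.sub(r"\.(hdr|img|dat|raw)$", "", path)
    data = np.asarray(cube.data)
    if data.dtype not in _DTYPE_CODES:
        data = data.astype(np.float64)
    rows, cols, bands = data.shape
    hdr = [
        "ENVI",
        "description = {fishspec synthetic hypercube}",
        f"samples = {cols}",
        f"lines = {rows}",
        f"bands = {bands}",
        "header offset = 0",
        "file type = ENVI Standard",
        f"data type = {_DTYPE_CODES[data.dtype]}",
        f"interleave = {interleave}",
        "byte order = 0",
        f"mode = {cube.mode}",
        f"exposure ms = {cube.exposure_ms}",
        "wavelength = {" + ", ".join(f"{w:.4f}" for w in cube.wavelengths) + "}",
    ]
    with open(base + ".hdr", "w") as fh:
        fh.write("\n".join(hdr) + "\n")
    np.transpose(data, _INTERLEAVE_AXES[interleave]).tofile(base + ".img")
    return base + ".hdr", base + ".img"
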