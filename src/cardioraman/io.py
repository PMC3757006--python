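"""Reading and writing spectrum files.

Two dialects are supported:

``two_column``
    Whitespace- or comma-delimited text with one ``shift intensity``
    pair per line; ``#`` starts a comment.  Metadata may be embedded in
    leading ``# key: value`` comment lines and is restored on read.

``jcamp_dx``
    A minimal JCAMP-DX subset: LDRs (``##TITLE=`` etc.), x-units in
    1/CM, and an ``##XYDATA=(X++(Y..Y))`` table (the ``(XY..XY)``
    variant is also read).  Enough for exchange with spectrometer
    software; compressed (DIF/DUP) forms are not supported.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Literal

import numpy as np

from .errors import SpectrumFormatError, ValidationError
from .spectrum import RamanSpectrum

Dialect = Literal["two_column", "jcamp_dx"]

_NUM = r"[-+]?\d+(?:\.\d*)?(?:[eE][-+]?\d+)?"


def read_spectrum(path, dialect: Dialect = "two_column") -> RamanSpectrum:
    """Read a spectrum file; shifts are returned sorted ascending."""
    path = Path(path)
    text = path.read_text()
    if dialect == "two_column":
        shifts, intens, meta = _parse_two_column(text, path)
    elif dialect == "jcamp_dx":
        shifts, intens, meta = _parse_jcamp(text, path)
    else:
        raise ValidationError(f"unknown dialect {dialect!r}")
    order = np.argsort(shifts, kind="stable")
    shifts = shifts[order]
    intens = intens[order]
    if np.any(np.diff(shifts) == 0):
        dup = shifts[:-1][np.diff(shifts) == 0][0]
        raise ValidationError(f"{path}: duplicated shift value {dup:g} cm⁻¹")
    return RamanSpectrum(shifts, intens, meta)


def write_spectrum(spectrum: RamanSpectrum, path, dialect: Dialect = "two_column") -> None:
    """Write a spectrum so that :func:`read_spectrum` reproduces it.

    Metadata is preserved for both dialects (``# key: value`` comments
    for ``two_column``, ``##$KEY=value`` user LDRs for ``jcamp_dx``).
    """
    path = Path(path)
    if dialect == "two_column":
        lines = [f"# {k}: {v}" for k, v in spectrum.meta.items()]
        lines += [
            f"{s:.9g} {i:.12g}"
            for s, i in zip(spectrum.shifts, spectrum.intensities)
        ]
        path.write_text("\n".join(lines) + "\n")
    elif dialect == "jcamp_dx":
        path.write_text(_format_jcamp(spectrum))
    else:
        raise ValidationError(f"unknown dialect {dialect!r}")


def _parse_two_column(text: str, path) -> tuple[np.ndarray, np.ndarray, dict]:
    shifts: list[float] = []
    intens: list[float] = []
    meta: dict[str, str] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, value = body.partition(":")
                meta[key.strip()] = value.strip()
            continue
        parts = re.split(r"[,\s]+", line)
        if len(parts) != 2:
            raise SpectrumFormatError(
                f"expected 2 columns, found {len(parts)}: {line!r}", path, lineno
            )
        try:
            shifts.append(float(parts[0]))
            intens.append(float(parts[1]))
        except ValueError:
            raise SpectrumFormatError(f"non-numeric value in {line!r}", path, lineno)
    if len(shifts) < 2:
        raise SpectrumFormatError("fewer than 2 data rows", path)
    return np.array(shifts), np.array(intens), meta


_JCAMP_RESERVED = {
    "TITLE", "JCAMP-DX", "DATA TYPE", "DATATYPE", "XUNITS", "YUNITS",
    "XFACTOR", "YFACTOR", "FIRSTX", "LASTX", "NPOINTS", "XYDATA", "END",
}


def _parse_jcamp(text: str, path) -> tuple[np.ndarray, np.ndarray, dict]:
    meta: dict[str, str] = {}
    xfactor = 1.0
    yfactor = 1.0
    data_mode: str | None = None
    xs: list[float] = []
    ys: list[float] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("$$"):
            continue
        if line.startswith("##"):
            key, _, value = line[2:].partition("=")
            key = key.strip().upper()
            value = value.strip()
            if key == "XFACTOR":
                xfactor = float(value)
            elif key == "YFACTOR":
                yfactor = float(value)
            elif key == "XYDATA":
                table = value.replace(" ", "").upper()
                if table == "(X++(Y..Y))":
                    data_mode = "x_plus_y"
                elif table == "(XY..XY)":
                    data_mode = "xy_pairs"
                else:
                    raise SpectrumFormatError(
                        f"unsupported XYDATA table {value!r}", path, lineno
                    )
            elif key == "END":
                data_mode = None
            elif key.startswith("$"):
                meta[key[1:].lower()] = value
            elif key not in _JCAMP_RESERVED:
                meta[key.lower()] = value
            continue
        if data_mode is None:
            raise SpectrumFormatError(f"data outside an XYDATA block: {line!r}", path, lineno)
        nums = re.findall(_NUM, line.replace(",", " "))
        if not nums:
            raise SpectrumFormatError(f"no numeric data in {line!r}", path, lineno)
        vals = [float(v) for v in nums]
        if data_mode == "x_plus_y":
            # first number on the line is X of the first Y; subsequent Ys
            # are at implicit equal X increments fixed later from FIRSTX/LASTX
            xs.append(vals[0])
            ys.extend(vals[1:])
        else:
            if len(vals) % 2:
                raise SpectrumFormatError(
                    f"odd number of values in XY pair line: {line!r}", path, lineno
                )
            xs.extend(vals[0::2])
            ys.extend(vals[1::2])
    if len(ys) < 2:
        raise SpectrumFormatError("fewer than 2 data points", path)
    if len(xs) == len(ys):
        shifts = np.array(xs) * xfactor
    else:
        # X++(Y..Y): reconstruct the grid from line-start abscissae
        shifts = _reconstruct_grid(np.array(xs) * xfactor, _line_counts(text), len(ys))
    return shifts, np.array(ys) * yfactor, meta


def _line_counts(text: str) -> list[int]:
    counts = []
    in_data = False
    for raw in text.splitlines():
        line = raw.strip()
        if line.upper().startswith("##XYDATA"):
            in_data = True
            continue
        if line.startswith("##"):
            in_data = False
            continue
        if in_data and line:
            counts.append(len(re.findall(_NUM, line)) - 1)
    return counts


def _reconstruct_grid(line_x: np.ndarray, line_ny: list[int], total: int) -> np.ndarray:
    if len(line_x) > 1:
        step = (line_x[1] - line_x[0]) / line_ny[0]
    else:
        step = 1.0
    shifts = []
    for x0, n in zip(line_x, line_ny):
        shifts.extend(x0 + step * np.arange(n))
    return np.asarray(shifts[:total])


def _format_jcamp(spectrum: RamanSpectrum) -> str:
    lines = [
        f"##TITLE={spectrum.meta.get('title', 'Raman spectrum')}",
        "##JCAMP-DX=4.24",
        "##DATA TYPE=RAMAN SPECTRUM",
        "##XUNITS=1/CM",
        "##YUNITS=ARBITRARY UNITS",
        "##XFACTOR=1",
        "##YFACTOR=1",
        f"##FIRSTX={spectrum.shifts[0]:.9g}",
        f"##LASTX={spectrum.shifts[-1]:.9g}",
        f"##NPOINTS={len(spectrum)}",
    ]
    for key, value in spectrum.meta.items():
        if key == "title":
            continue
        lines.append(f"##${key.upper()}={value}")
    lines.append("##XYDATA=(XY..XY)")
    for s, i in zip(spectrum.shifts, spectrum.intensities):
        lines.append(f"{s:.9g}, {i:.12g}")
    lines.append("##END=")
    return "\n".join(lines) + "\n"
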