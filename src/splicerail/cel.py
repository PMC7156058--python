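"""Reading and writing Affymetrix CEL version-4 binary files.

The version-4 CEL format is a little-endian binary container holding, for
every cell (probe location) on the chip, the mean fluorescence intensity of
the pixels covering the feature, their standard deviation and the pixel
count.  The layout implemented here follows the GCOS file specification:

====================  =======================================================
field                 encoding
====================  =======================================================
magic                 int32, always 64
version               int32, always 4
n_cols, n_rows        int32 each
n_cells               int32, must equal ``n_cols * n_rows``
header                int32 length + ASCII text (``key=value`` lines)
algorithm             int32 length + ASCII text
parameters            int32 length + ASCII text
cell margin           int32
n_outliers            uint32
n_masked              uint32
n_subgrids            int32
cells                 ``n_cells`` records of (float32 mean, float32 stdev,
                      int16 pixel count), row-major (y major, x minor)
masked entries        ``n_masked`` records of (int16 x, int16 y)
outlier entries       ``n_outliers`` records of (int16 x, int16 y)
sub-grids             preserved as an opaque byte trailer, not interpreted
====================  =======================================================

Only version 4 is supported.  Version-3 files (text, starting ``[CEL]``) and
Command Console files (binary, magic 59) are rejected with a clear message.
Sub-grid, outlier and mask sections are carried through opaquely: the
analysis pipeline consumes mean intensities only.

A plain-text tabular path (probe rows x participant columns) is provided in
:mod:`splicerail.preprocess` for users without binary files.
"""

from __future__ import annotations

import io
import struct
from dataclasses import dataclass, field

import numpy as np

MAGIC_V4 = 64
VERSION_V4 = 4

_CELL_DTYPE = np.dtype([("mean", "<f4"), ("stdev", "<f4"), ("pixels", "<i2")])
_XY_DTYPE = np.dtype([("x", "<i2"), ("y", "<i2")])

#: Default header template.  ``Cols``/``Rows`` are substituted on write; the
#: remaining keys mirror what scanner software emits and are required by some
#: third-party readers.
_HEADER_TEMPLATE = (
    "Cols={cols}\n"
    "Rows={rows}\n"
    "TotalX={cols}\nTotalY={rows}\n"
    "OffsetX=0\nOffsetY=0\n"
    "GridCornerUL=0 0\nGridCornerUR=0 0\nGridCornerLR=0 0\nGridCornerLL=0 0\n"
    "Axis-invertX=0\nAxisInvertY=0\nswapXY=0\n"
    "DatHeader=synthetic\n"
    "Algorithm=Percentile\n"
    "AlgorithmParameters=CellMargin:4\n"
)


def default_header(n_cols: int, n_rows: int) -> str:
    """A scanner-style ``key=value`` header for a grid of the given shape."""
    return _HEADER_TEMPLATE.format(cols=n_cols, rows=n_rows)


class CelFormatError(ValueError):
    """Raised when a byte stream is not a well-formed CEL version-4 file."""


@dataclass
class CelMatrix:
    """In-memory image of one CEL v4 file.

    ``mean_intensity``, ``stdev`` and ``pixel_count`` are ``(n_rows, n_cols)``
    grids; a probe with chip coordinates ``(x, y)`` lives at ``grid[y, x]``.
    """

    n_cols: int
    n_rows: int
    mean_intensity: np.ndarray
    stdev: np.ndarray
    pixel_count: np.ndarray
    header_text: str = ""
    algorithm: str = "Percentile"
    parameters: str = "CellMargin:4"
    cell_margin: int = 4
    masked: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=_XY_DTYPE))
    outliers: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=_XY_DTYPE))
    subgrid_trailer: bytes = b""

    def __post_init__(self) -> None:
        shape = (self.n_rows, self.n_cols)
        for name in ("mean_intensity", "stdev", "pixel_count"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != shape:
                raise ValueError(
                    f"{name} has shape {arr.shape}, expected {shape} "
                    f"(n_rows x n_cols)"
                )
            setattr(self, name, arr)

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CelMatrix):
            return NotImplemented
        return (
            self.n_cols == other.n_cols
            and self.n_rows == other.n_rows
            and np.array_equal(self.mean_intensity, other.mean_intensity)
            and np.array_equal(self.stdev, other.stdev)
            and np.array_equal(self.pixel_count, other.pixel_count)
            and self.header_text == other.header_text
            and self.algorithm == other.algorithm
            and self.parameters == other.parameters
            and self.cell_margin == other.cell_margin
            and np.array_equal(self.masked, other.masked)
            and np.array_equal(self.outliers, other.outliers)
            and self.subgrid_trailer == other.subgrid_trailer
        )


def _read_exact(stream, n: int, what: str) -> bytes:
    offset = stream.tell()
    data = stream.read(n)
    if len(data) != n:
        raise CelFormatError(
            f"truncated CEL stream: needed {n} bytes for {what} at byte "
            f"offset {offset}, got {len(data)}"
        )
    return data


def _read_int(stream, what: str, fmt: str = "<i") -> int:
    return struct.unpack(fmt, _read_exact(stream, 4, what))[0]


def _read_string(stream, what: str) -> str:
    length = _read_int(stream, f"{what} length")
    if length < 0:
        raise CelFormatError(f"negative {what} length {length}")
    return _read_exact(stream, length, what).decode("ascii", "replace")


def read_cel_v4(source) -> CelMatrix:
    """Parse a CEL version-4 byte stream (or bytes, or a file path).

    Raises
    ------
    CelFormatError
        If the magic number is not 64, the version is not 4, or the stream
        is truncated (the error names the offending field / byte offset).
    """
    if isinstance(source, (str, bytes)) and not isinstance(source, bytes):
        with open(source, "rb") as fh:
            return read_cel_v4(fh.read())
    if isinstance(source, bytes):
        source = io.BytesIO(source)

    head = _read_exact(source, 4, "magic number")
    if head == b"[CEL":
        raise CelFormatError(
            "stream looks like a text (version 3) CEL file; only the "
            "version 4 binary format is supported"
        )
    (magic,) = struct.unpack("<i", head)
    if magic == 59:
        raise CelFormatError(
            "magic number 59 denotes an Affymetrix Command Console file; "
            "only CEL version 4 (magic 64) is supported"
        )
    if magic != MAGIC_V4:
        raise CelFormatError(f"bad magic number {magic}, expected {MAGIC_V4}")
    version = _read_int(source, "version")
    if version != VERSION_V4:
        raise CelFormatError(f"bad version {version}, expected {VERSION_V4}")

    n_cols = _read_int(source, "column count")
    n_rows = _read_int(source, "row count")
    n_cells = _read_int(source, "cell count")
    if n_cols < 0 or n_rows < 0:
        raise CelFormatError(f"negative grid dimensions {n_rows}x{n_cols}")
    if n_cells != n_cols * n_rows:
        raise CelFormatError(
            f"declared cell count {n_cells} does not equal "
            f"n_cols*n_rows = {n_cols * n_rows}"
        )

    header_text = _read_string(source, "header")
    algorithm = _read_string(source, "algorithm")
    parameters = _read_string(source, "algorithm parameters")
    cell_margin = _read_int(source, "cell margin")
    n_outliers = _read_int(source, "outlier count", "<I")
    n_masked = _read_int(source, "masked count", "<I")
    _read_int(source, "sub-grid count")  # trailer kept opaque below

    raw = _read_exact(source, _CELL_DTYPE.itemsize * n_cells, "cell records")
    cells = np.frombuffer(raw, dtype=_CELL_DTYPE)
    masked = np.frombuffer(
        _read_exact(source, _XY_DTYPE.itemsize * n_masked, "masked entries"),
        dtype=_XY_DTYPE,
    )
    outliers = np.frombuffer(
        _read_exact(source, _XY_DTYPE.itemsize * n_outliers, "outlier entries"),
        dtype=_XY_DTYPE,
    )
    trailer = source.read()

    shape = (n_rows, n_cols)
    return CelMatrix(
        n_cols=n_cols,
        n_rows=n_rows,
        mean_intensity=cells["mean"].astype(np.float32).reshape(shape),
        stdev=cells["stdev"].astype(np.float32).reshape(shape),
        pixel_count=cells["pixels"].astype(np.int16).reshape(shape),
        header_text=header_text,
        algorithm=algorithm,
        parameters=parameters,
        cell_margin=cell_margin,
        masked=masked.copy(),
        outliers=outliers.copy(),
        subgrid_trailer=trailer,
    )


def write_cel_v4(m: CelMatrix) -> bytes:
    """Serialise a :class:`CelMatrix` to CEL version-4 bytes.

    The output parses back to an equal matrix (mean/stdev are stored as
    4-byte floats, so values are rounded to float32 precision on write).
    """
    shape = (m.n_rows, m.n_cols)
    for name in ("mean_intensity", "stdev", "pixel_count"):
        arr = np.asarray(getattr(m, name))
        if arr.shape != shape:
            raise ValueError(f"{name} shape {arr.shape} != grid shape {shape}")

    out = io.BytesIO()
    out.write(struct.pack("<ii", MAGIC_V4, VERSION_V4))
    out.write(struct.pack("<iii", m.n_cols, m.n_rows, m.n_cells))
    for text in (m.header_text, m.algorithm, m.parameters):
        data = text.encode("ascii")
        out.write(struct.pack("<i", len(data)))
        out.write(data)
    out.write(struct.pack("<i", m.cell_margin))
    out.write(struct.pack("<II", len(m.outliers), len(m.masked)))
    out.write(struct.pack("<i", 0))

    cells = np.empty(m.n_cells, dtype=_CELL_DTYPE)
    cells["mean"] = np.asarray(m.mean_intensity, dtype=np.float32).ravel()
    cells["stdev"] = np.asarray(m.stdev, dtype=np.float32).ravel()
    cells["pixels"] = np.asarray(m.pixel_count, dtype=np.int16).ravel()
    out.write(cells.tobytes())
    out.write(np.asarray(m.masked, dtype=_XY_DTYPE).tobytes())
    out.write(np.asarray(m.outliers, dtype=_XY_DTYPE).tobytes())
    out.write(m.subgrid_trailer)
    return out.getvalue()


def intensities_from_cel(m: CelMatrix, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Mean intensities at chip coordinates ``(x, y)`` (vectorised lookup)."""
    x = np.asarray(x, dtype=int)
    y = np.asarray(y, dtype=int)
    if np.any(x < 0) or np.any(x >= m.n_cols) or np.any(y < 0) or np.any(y >= m.n_rows):
        raise IndexError("probe chip coordinates fall outside the CEL grid")
    return np.asarray(m.mean_intensity)[y, x]
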