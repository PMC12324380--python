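"""File formats: MRC2014 image stacks, STAR tables, delimited metadata tables.

MRC2014 is the electron-microscopy standard binary image/volume format: a
1024-byte fixed header (plus optional extended header) followed by the raster.
A stack of N 2D class averages is stored as an NX x NY x NZ volume with one
class per Z section. STAR files are the plain-text block/loop tabular format
used by RELION for all particle and class metadata.

Dialect rules implemented here:

* MRC written as mode 2 (float32), little-endian; modes 0/1/2/6 accepted on
  read and converted to float32. Pixel size is CELLA / M? per axis and must
  be isotropic in x/y within 1e-3 relative.
* STAR: a single ``data_`` block with one ``loop_``; tags are
  underscore-prefixed; image references use the RELION ``NNNNNN@stack.mrcs``
  convention with a 1-based slice index (slices are 0-based everywhere else
  in this package).
* Metadata tables may be STAR, CSV or TSV; column synonyms are mapped onto
  the canonical record fields below.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import FormatError, SchemaError, ValidationError

__all__ = [
    "ClassAverageStack",
    "ClassRecord",
    "ScoreTable",
    "read_class_stack",
    "write_class_stack",
    "read_score_star",
    "write_score_star",
    "read_metadata_table",
    "write_metadata_star",
    "read_star",
    "write_star",
    "format_image_ref",
    "parse_image_ref",
    "SCORE_TAG",
    "BIN_SCORE_TAG",
    "IMAGE_TAG",
]

# STAR column tags for score tables. RELION has no canonical tag for an
# external class-quality score, so the package defines its own, documented
# here and in the README.
IMAGE_TAG = "_rlnReferenceImage"
SCORE_TAG = "_sift2dScore"
BIN_SCORE_TAG = "_sift2dBinScore"

_MRC_HEADER_BYTES = 1024
_MRC_MODE_DTYPES = {
    0: np.dtype("<i1"),
    1: np.dtype("<i2"),
    2: np.dtype("<f4"),
    6: np.dtype("<u2"),
}


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------


@dataclass
class ClassAverageStack:
    """An ordered stack of 2D class-average images sharing one pixel size.

    Parameters
    ----------
    images : (N, H, W) float32 array
        One 2D class average per leading index.
    pixel_size : float
        Sampling in Angstrom per pixel; strictly positive.
    source_path : str
        Provenance string (file the stack was read from, or a label).
    """

    images: np.ndarray
    pixel_size: float
    source_path: str = ""

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=np.float32)
        if self.images.ndim == 2:
            self.images = self.images[None]
        if self.images.ndim != 3:
            raise ValidationError(
                f"stack must be (N, H, W); got shape {self.images.shape}"
            )
        if self.pixel_size <= 0:
            raise ValidationError(f"pixel_size must be > 0, got {self.pixel_size}")
        if not np.all(np.isfinite(self.images)):
            raise ValidationError("stack contains non-finite pixel values")

    def __len__(self) -> int:
        return self.images.shape[0]

    def __getitem__(self, i: int) -> np.ndarray:
        return self.images[i]


@dataclass
class ClassRecord:
    """Metadata for one 2D class.

    ``frc_resolution`` is the Fourier-ring-correlation resolution estimate in
    Angstrom (larger = worse); ``class_distribution`` is the fraction of the
    job's particles assigned to this class. ``mass_kda`` and ``label`` are
    optional until filled by the mass estimator / an annotator.
    """

    class_index: int
    pixel_size: float
    frc_resolution: float
    class_distribution: float
    image_ref: tuple[str, int] = ("", -1)
    mass_kda: Optional[float] = None
    label: Optional[float] = None

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValidationError(
                f"class {self.class_index}: pixel_size must be > 0, got {self.pixel_size}"
            )
        if self.frc_resolution <= 0:
            raise ValidationError(
                f"class {self.class_index}: frc_resolution must be > 0, "
                f"got {self.frc_resolution}"
            )
        if not 0.0 <= self.class_distribution <= 1.0:
            raise ValidationError(
                f"class {self.class_index}: class_distribution must lie in [0, 1], "
                f"got {self.class_distribution}"
            )


@dataclass
class ScoreTable:
    """Per-class continuous quality scores, ordered like the input stack.

    Scores are open-ended reals (1.0 best ... 5.0 worst by convention, but
    never clamped); ``bin_scores`` optionally holds the [0, 1] bin-converted
    values.
    """

    class_indices: list[int] = field(default_factory=list)
    image_refs: list[tuple[str, int]] = field(default_factory=list)
    scores: list[float] = field(default_factory=list)
    bin_scores: Optional[list[float]] = None

    def __post_init__(self) -> None:
        n = len(self.class_indices)
        if len(self.image_refs) != n or len(self.scores) != n:
            raise ValidationError("score table columns have unequal lengths")
        if self.bin_scores is not None and len(self.bin_scores) != n:
            raise ValidationError("bin_scores length mismatch")
        if n and not np.all(np.isfinite(self.scores)):
            raise ValidationError("scores must be finite")

    def __len__(self) -> int:
        return len(self.class_indices)

    def score_of(self, class_index: int) -> float:
        return self.scores[self.class_indices.index(class_index)]


# ---------------------------------------------------------------------------
# MRC2014
# ---------------------------------------------------------------------------


def _read_mrc_header(raw: bytes, path: str) -> dict:
    if len(raw) < _MRC_HEADER_BYTES:
        raise FormatError(f"{path}: file shorter than the 1024-byte MRC header")
    words_i = struct.unpack("<10i", raw[0:40])
    cella = struct.unpack("<3f", raw[40:52])
    mapc, mapr, maps_ = struct.unpack("<3i", raw[64:76])
    ispg, nsymbt = struct.unpack("<2i", raw[88:96])
    map_id = raw[208:212]
    hdr = {
        "nx": words_i[0],
        "ny": words_i[1],
        "nz": words_i[2],
        "mode": words_i[3],
        "mx": words_i[7],
        "my": words_i[8],
        "mz": words_i[9],
        "cella": cella,
        "mapc": mapc,
        "mapr": mapr,
        "maps": maps_,
        "ispg": ispg,
        "nsymbt": nsymbt,
        "map_id": map_id,
    }
    if hdr["nx"] <= 0 or hdr["ny"] <= 0 or hdr["nz"] <= 0:
        raise FormatError(
            f"{path}: malformed MRC header (dimensions "
            f"{hdr['nx']}x{hdr['ny']}x{hdr['nz']})"
        )
    if hdr["mode"] not in _MRC_MODE_DTYPES:
        raise FormatError(
            f"{path}: unsupported MRC mode {hdr['mode']} (accepted: 0, 1, 2, 6)"
        )
    # MAP stamp is required by MRC2014 but absent from some legacy writers;
    # reject only if present and wrong.
    if map_id not in (b"MAP ", b"\x00\x00\x00\x00"):
        raise FormatError(f"{path}: bad MAP stamp {map_id!r} in MRC header")
    return hdr


def read_class_stack(path: Union[str, Path]) -> ClassAverageStack:
    """Read an MRC2014 file as a stack of 2D class averages.

    A single 2D image (NZ == 1) yields a one-slice stack. The pixel size is
    taken from the header voxel size (CELLA / M per axis) and must agree
    between x and y within 1e-3 relative; a zero cell (legacy files) falls
    back to 1.0 A/px.
    """
    path = Path(path)
    raw = path.read_bytes()
    hdr = _read_mrc_header(raw, str(path))
    nx, ny, nz = hdr["nx"], hdr["ny"], hdr["nz"]
    dtype = _MRC_MODE_DTYPES[hdr["mode"]]
    offset = _MRC_HEADER_BYTES + max(hdr["nsymbt"], 0)
    nbytes = nx * ny * nz * dtype.itemsize
    if len(raw) < offset + nbytes:
        raise FormatError(
            f"{path}: truncated data block (expected {nbytes} bytes after header)"
        )
    data = np.frombuffer(raw, dtype=dtype, count=nx * ny * nz, offset=offset)
    images = data.reshape(nz, ny, nx).astype(np.float32)

    if hdr["mx"] > 0 and hdr["cella"][0] > 0:
        apix_x = hdr["cella"][0] / hdr["mx"]
        apix_y = hdr["cella"][1] / hdr["my"] if hdr["my"] > 0 else apix_x
        if abs(apix_x - apix_y) > 1e-3 * max(apix_x, apix_y):
            raise ValidationError(
                f"{path}: anisotropic pixel size (x: {apix_x:.6g} A/px, "
                f"y: {apix_y:.6g} A/px); only isotropic 2D classes are supported"
            )
        pixel_size = float(apix_x)
    else:
        pixel_size = 1.0

    if not np.all(np.isfinite(images)):
        raise ValidationError(f"{path}: stack contains non-finite pixel values")
    return ClassAverageStack(images=images, pixel_size=pixel_size, source_path=str(path))


def write_class_stack(stack: ClassAverageStack, path: Union[str, Path]) -> Path:
    """Write a stack as little-endian mode-2 (float32) MRC2014.

    ISPG is set to 0 (image stack), NVERSION to 20140, and the voxel size is
    encoded via CELLA = pixel_size * (NX, NY, NZ) with M? = N?.
    """
    path = Path(path)
    imgs = np.ascontiguousarray(stack.images, dtype="<f4")
    nz, ny, nx = imgs.shape
    apix = float(stack.pixel_size)

    hdr = bytearray(_MRC_HEADER_BYTES)
    struct.pack_into("<10i", hdr, 0, nx, ny, nz, 2, 0, 0, 0, nx, ny, nz)
    struct.pack_into("<3f", hdr, 40, nx * apix, ny * apix, nz * apix)
    struct.pack_into("<3f", hdr, 52, 90.0, 90.0, 90.0)
    struct.pack_into("<3i", hdr, 64, 1, 2, 3)
    struct.pack_into(
        "<3f", hdr, 76, float(imgs.min()), float(imgs.max()), float(imgs.mean())
    )
    struct.pack_into("<2i", hdr, 88, 0, 0)  # ispg=0 (stack), nsymbt=0
    struct.pack_into("<i", hdr, 108, 20140)  # nversion
    hdr[208:212] = b"MAP "
    hdr[212:216] = bytes([0x44, 0x44, 0x00, 0x00])  # little-endian stamp
    struct.pack_into("<f", hdr, 216, float(imgs.std()))
    struct.pack_into("<i", hdr, 220, 1)
    label = b"sift2d class-average stack"
    hdr[224 : 224 + len(label)] = label

    with open(path, "wb") as fh:
        fh.write(bytes(hdr))
        fh.write(imgs.tobytes())
    return path


# ---------------------------------------------------------------------------
# STAR
# ---------------------------------------------------------------------------


def read_star(path: Union[str, Path]) -> pd.DataFrame:
    """Parse the first loop of the first data_ block of a STAR file.

    Returns a DataFrame whose columns are the loop tags (with the leading
    underscore). Values are converted to numbers where possible.
    """
    path = Path(path)
    tags: list[str] = []
    rows: list[list[str]] = []
    state = "preamble"
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            if state == "preamble":
                if s.startswith("data_"):
                    state = "block"
                continue
            if state == "block":
                if s.startswith("loop_"):
                    state = "tags"
                continue
            if state == "tags":
                if s.startswith("_"):
                    tags.append(s.split()[0])
                    continue
                state = "rows"
            if state == "rows":
                if s.startswith("data_") or s.startswith("loop_") or s.startswith("_"):
                    break
                vals = s.split()
                if len(vals) != len(tags):
                    raise FormatError(
                        f"{path}:{lineno}: row has {len(vals)} values for "
                        f"{len(tags)} loop tags"
                    )
                rows.append(vals)
    if not tags:
        raise FormatError(f"{path}: no loop_ block found")
    df = pd.DataFrame(rows, columns=tags)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        if not converted.isna().any():
            df[col] = converted
    return df


def write_star(
    df: pd.DataFrame, path: Union[str, Path], block: str = "data_", comment: str = ""
) -> Path:
    """Write a DataFrame as a single-block, single-loop STAR file."""
    path = Path(path)
    lines = []
    if comment:
        lines.append(f"# {comment}")
    lines += ["", block, "", "loop_"]
    lines += [f"{col} #{i + 1}" for i, col in enumerate(df.columns)]
    for _, row in df.iterrows():
        cells = []
        for v in row:
            if isinstance(v, float) or isinstance(v, np.floating):
                cells.append(f"{v:.6f}" if abs(v) < 1e6 else repr(float(v)))
            else:
                cells.append(str(v))
        lines.append(" ".join(cells))
    path.write_text("\n".join(lines) + "\n")
    return path


def format_image_ref(slice_index: int, stack_name: str) -> str:
    """0-based slice index -> RELION ``NNNNNN@stack`` reference (1-based)."""
    return f"{slice_index + 1:06d}@{stack_name}"


def parse_image_ref(ref: str) -> tuple[str, int]:
    """RELION ``NNNNNN@stack`` reference -> (stack name, 0-based slice)."""
    if "@" not in ref:
        raise FormatError(f"not an image reference: {ref!r}")
    idx, name = ref.split("@", 1)
    return name, int(idx) - 1


def write_score_star(table: ScoreTable, path: Union[str, Path]) -> Path:
    """Write a score table as a STAR loop readable by ``relion_display``.

    Columns: ``_rlnReferenceImage`` (``NNNNNN@stack`` convention),
    ``_sift2dScore`` (continuous, lower = better) and, when present,
    ``_sift2dBinScore`` ([0, 1], higher = better). Scores round-trip to at
    least 6 significant digits.
    """
    if len(table) == 0:
        raise ValidationError("refusing to write an empty score table")
    cols = {
        IMAGE_TAG: [format_image_ref(i, name) for name, i in table.image_refs],
        SCORE_TAG: [f"{s:.8g}" for s in table.scores],
    }
    if table.bin_scores is not None:
        cols[BIN_SCORE_TAG] = [f"{b:.8g}" for b in table.bin_scores]
    df = pd.DataFrame(cols)
    return write_star(df, path, block="data_sift2d_scores")


def read_score_star(path: Union[str, Path]) -> ScoreTable:
    """Read a score STAR written by :func:`write_score_star`."""
    df = read_star(path)
    for col in (IMAGE_TAG, SCORE_TAG):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required STAR tag {col}")
    refs = [parse_image_ref(str(r)) for r in df[IMAGE_TAG]]
    scores = [float(s) for s in df[SCORE_TAG]]
    bins = (
        [float(b) for b in df[BIN_SCORE_TAG]] if BIN_SCORE_TAG in df.columns else None
    )
    return ScoreTable(
        class_indices=[i for _, i in refs],
        image_refs=refs,
        scores=scores,
        bin_scores=bins,
    )


# ---------------------------------------------------------------------------
# metadata tables (STAR / CSV / TSV)
# ---------------------------------------------------------------------------

# canonical field -> accepted column spellings (case-insensitive; the leading
# underscore of STAR tags is stripped before matching)
_COLUMN_SYNONYMS = {
    "pixel_size": ("pixel_size", "rlnpixelsize", "apix", "psize_a"),
    "frc_resolution": (
        "frc_resolution",
        "rlnestimatedresolution",
        "est_res_a",
        "resolution",
    ),
    "class_distribution": (
        "class_distribution",
        "rlnclassdistribution",
        "class_fraction",
    ),
    "class_index": ("class_index", "rlnclassnumber", "class"),
    "mass_kda": ("mass_kda", "mass", "sift2dmasskda"),
    "label": ("label", "score", "grade", "sift2dlabel"),
}

_GRADE_TO_SCORE = {"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0, "F": 5.0}

_REQUIRED_FIELDS = ("pixel_size", "frc_resolution", "class_distribution")


def _canonical_columns(df: pd.DataFrame) -> dict[str, str]:
    lookup = {}
    for col in df.columns:
        key = str(col).lstrip("_").lower()
        for field_name, synonyms in _COLUMN_SYNONYMS.items():
            if key in synonyms and field_name not in lookup:
                lookup[field_name] = col
    return lookup


def _parse_label(value) -> float:
    if isinstance(value, str) and value.strip().upper() in _GRADE_TO_SCORE:
        return _GRADE_TO_SCORE[value.strip().upper()]
    return float(value)


def read_metadata_table(
    path: Union[str, Path], renormalize_window: tuple[float, float] = (0.9, 1.1)
) -> list[ClassRecord]:
    """Read per-class metadata from a STAR, CSV or TSV file.

    Required columns (synonyms accepted): pixel size, FRC resolution,
    class distribution. Optional: class index, mass, label (numeric score or
    grade letter A/B/C/D/F, mapped to 1..5). Missing optional columns leave
    the corresponding record fields unset.

    Class distributions must sum to 1; a sum k inside ``renormalize_window``
    is renormalized (with a warning on stderr via warnings), outside it is an
    error.
    """
    import warnings

    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".star":
        df = read_star(path)
    elif suffix in (".csv", ".txt"):
        df = pd.read_csv(path)
    elif suffix in (".tsv", ".tab"):
        df = pd.read_csv(path, sep="\t")
    else:  # sniff: STAR files start with data_/# lines
        head = path.read_text().lstrip()
        df = read_star(path) if head.startswith(("data_", "#")) else pd.read_csv(path)

    lookup = _canonical_columns(df)
    for field_name in _REQUIRED_FIELDS:
        if field_name not in lookup:
            raise SchemaError(
                f"{path}: missing required column for '{field_name}' "
                f"(accepted spellings: {', '.join(_COLUMN_SYNONYMS[field_name])})"
            )

    def cell(row_i: int, field_name: str) -> float:
        raw = df.iloc[row_i][lookup[field_name]]
        try:
            return float(raw)
        except (TypeError, ValueError) as e:
            raise SchemaError(
                f"{path}: row {row_i + 1}: non-numeric value {raw!r} "
                f"in column {lookup[field_name]!r}"
            ) from e

    dist = np.array([cell(i, "class_distribution") for i in range(len(df))])
    total = dist.sum()
    if len(df) and not np.isclose(total, 1.0, atol=1e-6):
        lo, hi = renormalize_window
        if lo <= total <= hi:
            warnings.warn(
                f"{path}: class distributions sum to {total:.6g}; renormalizing",
                stacklevel=2,
            )
            dist = dist / total
        else:
            raise ValidationError(
                f"{path}: class distributions sum to {total:.6g}, outside the "
                f"tolerated window [{lo}, {hi}]"
            )

    records = []
    for i in range(len(df)):
        idx = int(cell(i, "class_index")) if "class_index" in lookup else i
        label = None
        if "label" in lookup:
            raw = df.iloc[i][lookup["label"]]
            if not (isinstance(raw, float) and np.isnan(raw)):
                label = _parse_label(raw)
        records.append(
            ClassRecord(
                class_index=idx,
                pixel_size=cell(i, "pixel_size"),
                frc_resolution=cell(i, "frc_resolution"),
                class_distribution=float(dist[i]),
                mass_kda=cell(i, "mass_kda") if "mass_kda" in lookup else None,
                label=label,
            )
        )
    return records


def write_metadata_star(records: Sequence[ClassRecord], path: Union[str, Path]) -> Path:
    """Write ClassRecords as a STAR metadata table (RELION-style tags)."""
    df = pd.DataFrame(
        {
            "_rlnClassNumber": [r.class_index for r in records],
            "_rlnPixelSize": [r.pixel_size for r in records],
            "_rlnEstimatedResolution": [r.frc_resolution for r in records],
            "_rlnClassDistribution": [r.class_distribution for r in records],
        }
    )
    if any(r.mass_kda is not None for r in records):
        df["_sift2dMassKda"] = [
            r.mass_kda if r.mass_kda is not None else float("nan") for r in records
        ]
    if any(r.label is not None for r in records):
        df["_sift2dLabel"] = [
            r.label if r.label is not None else float("nan") for r in records
        ]
    return write_star(df, path, block="data_sift2d_metadata")
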