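"""Domain data model and file input/output.

The analysis operates on 8-channel resting-state EEG (10-20 positions
F3, F4, T3, T4, C3, C4, O1, O2) recorded in eyes-closed (EC) and
eyes-open (EO) blocks, with per-subject demographics used as covariates.
All signal amplitudes are microvolts.

Two on-disk recording formats are supported:

* ``fixture`` — a small container with a JSON text header plus
  zlib-compressed little-endian float64 samples; round trips exactly,
  which is what the test suite relies on.
* ``edf`` — 16-bit European Data Format, one data record per second.
  Reading goes through :mod:`mne`; writing uses a minimal EDF encoder,
  so round trips are exact only up to the 16-bit quantization step of
  the stored physical range.
"""

from __future__ import annotations

import json
import struct
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    ChannelError,
    FormatError,
    ParseError,
    ValidationError,
)

DEFAULT_CHANNELS: tuple[str, ...] = ("F3", "F4", "T3", "T4", "C3", "C4", "O1", "O2")
CONDITIONS: tuple[str, ...] = ("EC", "EO")
#: condition tags a feature column may carry (ECminusEO = EC − EO difference)
CONDITION_TAGS: tuple[str, ...] = ("EC", "EO", "ECminusEO")

EDUCATION_LEVELS: dict[str, int] = {"P": 1, "J": 2, "S": 3, "A": 4, "U": 5}
_EDUCATION_CODES = {v: k for k, v in EDUCATION_LEVELS.items()}

_FIXTURE_MAGIC = b"REEG01\n"


def _normalize_channel(name: str) -> str:
    """Canonical channel label: case-insensitive, 'EEG ' prefix stripped."""
    name = name.strip()
    if name.upper().startswith("EEG "):
        name = name[4:].strip()
    return name.upper()


@dataclass(frozen=True)
class ChannelLayout:
    """Ordered channel labels of a montage."""

    names: tuple[str, ...] = DEFAULT_CHANNELS

    def __post_init__(self) -> None:
        names = tuple(str(n) for n in self.names)
        object.__setattr__(self, "names", names)
        if len(names) < 2:
            raise ValidationError("a layout needs at least 2 channels")
        if len({_normalize_channel(n) for n in names}) != len(names):
            raise ValidationError(f"duplicate channel labels in {names}")

    def __len__(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        key = _normalize_channel(name)
        for i, n in enumerate(self.names):
            if _normalize_channel(n) == key:
                return i
        raise ChannelError(f"channel {name!r} not in layout {self.names}")


@dataclass
class Recording:
    """One subject-condition continuous multichannel signal, in microvolts."""

    subject_id: str
    condition: str
    fs: float
    data: np.ndarray
    layout: ChannelLayout = field(default_factory=ChannelLayout)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.condition not in CONDITIONS:
            raise ValidationError(f"condition must be one of {CONDITIONS}, got {self.condition!r}")
        if not self.fs > 0:
            raise ValidationError(f"sampling rate must be positive, got {self.fs}")
        if self.data.ndim != 2:
            raise ValidationError("data must be channels x samples")
        if self.data.shape[0] != len(self.layout):
            raise ValidationError(
                f"data has {self.data.shape[0]} rows but layout has {len(self.layout)} channels"
            )
        if self.data.shape[1] == 0:
            raise ValidationError("zero-length recording")
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("recording contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel(self, name: str) -> np.ndarray:
        return self.data[self.layout.index(name)]

    def copy_with(self, **kwargs) -> "Recording":
        return replace(self, **kwargs)


@dataclass
class EpochedRecording:
    """Fixed-length epochs (epoch x channel x sample) cut from a Recording.

    ``source_indices`` tracks which original epoch positions the current
    epochs came from, so rejection and middle-selection stay auditable.
    """

    subject_id: str
    condition: str
    fs: float
    epochs: np.ndarray
    epoch_length_s: float
    layout: ChannelLayout = field(default_factory=ChannelLayout)
    source_indices: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=np.float64)
        if self.epochs.ndim != 3:
            raise ValidationError("epochs must be epoch x channel x sample")
        if self.epochs.shape[0] < 1:
            raise ValidationError("at least one epoch required")
        if self.epochs.shape[1] != len(self.layout):
            raise ValidationError("epoch channel count does not match layout")
        expect = int(round(self.epoch_length_s * self.fs))
        if self.epochs.shape[2] != expect:
            raise ValidationError(
                f"epochs have {self.epochs.shape[2]} samples, expected {expect}"
            )
        if self.source_indices is None:
            self.source_indices = np.arange(self.epochs.shape[0])
        else:
            self.source_indices = np.asarray(self.source_indices, dtype=int)
            if self.source_indices.shape != (self.epochs.shape[0],):
                raise ValidationError("source_indices length must equal epoch count")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.epochs.shape[1]

    def concatenate(self) -> np.ndarray:
        """Channels x samples array of all epochs glued back to back."""
        return np.concatenate(list(self.epochs), axis=1) if self.n_epochs > 1 else self.epochs[0]


@dataclass(frozen=True)
class SubjectMeta:
    """Demographics used as nuisance covariates in the group statistics."""

    subject_id: str
    group: str  # AD | HC
    age: float
    sex: str  # M | F
    education: int  # 1 (primary) .. 5 (university)
    handedness: str  # L | R

    def __post_init__(self) -> None:
        if self.group not in ("AD", "HC"):
            raise ValidationError(f"group must be AD or HC, got {self.group!r}")
        if self.sex not in ("M", "F"):
            raise ValidationError(f"sex must be M or F, got {self.sex!r}")
        if self.handedness not in ("L", "R"):
            raise ValidationError(f"handedness must be L or R, got {self.handedness!r}")
        if not self.age > 0:
            raise ValidationError(f"age must be positive, got {self.age}")
        if int(self.education) not in _EDUCATION_CODES:
            raise ValidationError(f"education must be 1..5, got {self.education}")


@dataclass(frozen=True)
class BandDefinition:
    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not (0 <= self.f_lo < self.f_hi):
            raise ValidationError(f"band {self.name}: need 0 <= f_lo < f_hi")


#: delta/theta/alpha/beta as used throughout; gamma deliberately excluded
#: (muscle contamination dominates above 30 Hz in scalp EEG).
CANONICAL_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 0.1, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 13.0),
    BandDefinition("beta", 13.0, 30.0),
)


def get_band(name: str, bands: Sequence[BandDefinition] = CANONICAL_BANDS) -> BandDefinition:
    for b in bands:
        if b.name == name:
            return b
    raise KeyError(name)


# ---------------------------------------------------------------------------
# feature-name grammar: "<metric>_<band>_<item>_<condition>"
# item is a channel ("F3") or an unordered pair ("F3-T4");
# condition is EC, EO or ECminusEO.
# ---------------------------------------------------------------------------

def format_feature_name(metric: str, band: str, item: str | tuple[str, str], condition: str) -> str:
    if isinstance(item, tuple):
        item = f"{item[0]}-{item[1]}"
    parts = (metric, band, item, condition)
    for p in parts:
        if "_" in p or not p:
            raise ValidationError(f"feature-name token {p!r} must be non-empty and underscore-free")
    if condition not in CONDITION_TAGS:
        raise ValidationError(f"condition tag must be one of {CONDITION_TAGS}")
    return "_".join(parts)


def parse_feature_name(name: str) -> tuple[str, str, str | tuple[str, str], str]:
    parts = name.split("_")
    if len(parts) != 4:
        raise ParseError(f"feature name {name!r} is not metric_band_item_condition")
    metric, band, item, condition = parts
    if condition not in CONDITION_TAGS:
        raise ParseError(f"unknown condition tag in {name!r}")
    if "-" in item:
        a, b = item.split("-", 1)
        return metric, band, (a, b), condition
    return metric, band, item, condition


class FeatureTable:
    """Subjects x named scalar features.

    Thin wrapper over a pandas DataFrame indexed by subject_id whose
    column names all obey the feature-name grammar.
    """

    def __init__(self, df: pd.DataFrame):
        if df.index.has_duplicates:
            raise ValidationError("duplicate subject_id rows")
        if df.columns.has_duplicates:
            raise ValidationError("duplicate feature columns")
        for c in df.columns:
            parse_feature_name(str(c))
        values = df.to_numpy(dtype=float) if df.size else np.empty(df.shape)
        if df.size and not np.all(np.isfinite(values)):
            raise ValidationError("feature table contains NaN/inf cells")
        self.df = df.astype(float)
        self.df.index.name = "subject_id"

    @property
    def subjects(self) -> list[str]:
        return [str(s) for s in self.df.index]

    @property
    def feature_names(self) -> list[str]:
        return [str(c) for c in self.df.columns]

    def condition_slice(self, tag: str) -> "FeatureTable":
        cols = [c for c in self.feature_names if parse_feature_name(c)[3] == tag]
        return FeatureTable(self.df[cols].copy())

    @staticmethod
    def from_records(records: dict[str, dict[str, float]]) -> "FeatureTable":
        df = pd.DataFrame.from_dict(records, orient="index")
        return FeatureTable(df)

    @staticmethod
    def concat(tables: Iterable["FeatureTable"]) -> "FeatureTable":
        dfs = [t.df for t in tables]
        return FeatureTable(pd.concat(dfs, axis=1))

    def __eq__(self, other) -> bool:
        return isinstance(other, FeatureTable) and self.df.equals(other.df)


def write_feature_table(table: FeatureTable, path: str | Path) -> Path:
    path = Path(path)
    table.df.to_csv(path, float_format="%.17g")
    return path


def read_feature_table(path: str | Path) -> FeatureTable:
    try:
        df = pd.read_csv(path, index_col="subject_id")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"cannot read feature table {path}: {exc}") from exc
    if df.isna().any().any():
        raise FormatError(f"feature table {path} has missing/ragged cells")
    return FeatureTable(df)


# ---------------------------------------------------------------------------
# subject metadata CSV
# ---------------------------------------------------------------------------

_META_COLUMNS = ["subject_id", "group", "age", "sex", "education", "handedness"]


def read_metadata(path: str | Path) -> list[SubjectMeta]:
    """Read a subject table; education letters P/J/S/A/U map to 1..5."""
    try:
        df = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError:
        return []
    if df.empty:
        return []
    missing = [c for c in _META_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"metadata file missing columns {missing}")
    metas: list[SubjectMeta] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        sid = str(row["subject_id"]).strip()
        if sid in seen:
            raise ParseError(f"duplicate subject_id {sid!r}")
        seen.add(sid)
        group = str(row["group"]).strip()
        if group not in ("AD", "HC"):
            raise ParseError(f"unknown group label {group!r} for subject {sid}")
        edu_raw = str(row["education"]).strip()
        if edu_raw.upper() in EDUCATION_LEVELS:
            edu = EDUCATION_LEVELS[edu_raw.upper()]
        else:
            try:
                edu = int(edu_raw)
            except ValueError:
                raise ParseError(f"unknown education level {edu_raw!r}") from None
        try:
            meta = SubjectMeta(
                subject_id=sid,
                group=group,
                age=float(row["age"]),
                sex=str(row["sex"]).strip(),
                education=edu,
                handedness=str(row["handedness"]).strip(),
            )
        except (ValidationError, ValueError) as exc:
            raise ParseError(f"bad metadata row for {sid}: {exc}") from exc
        metas.append(meta)
    return metas


def write_metadata(metas: Sequence[SubjectMeta], path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        {
            "subject_id": [m.subject_id for m in metas],
            "group": [m.group for m in metas],
            "age": [m.age for m in metas],
            "sex": [m.sex for m in metas],
            "education": [_EDUCATION_CODES[int(m.education)] for m in metas],
            "handedness": [m.handedness for m in metas],
        }
    )
    df.to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# recording files
# ---------------------------------------------------------------------------

def write_recording(rec: Recording, path: str | Path, format: str = "fixture") -> Path:
    path = Path(path)
    if format == "fixture":
        _write_fixture(rec, path)
    elif format == "edf":
        _write_edf(rec, path)
    else:
        raise ValueError(f"unknown format {format!r}")
    return path


def read_recording(path: str | Path, format: str = "fixture") -> Recording:
    """Read a recording and reorder its rows to the default 8-channel layout.

    Extra channels are dropped; a missing required channel raises
    :class:`ChannelError`.
    """
    path = Path(path)
    if format == "fixture":
        return _read_fixture(path)
    if format == "edf":
        return _read_edf(path)
    raise ValueError(f"unknown format {format!r}")


def _reorder_to_layout(
    data: np.ndarray, names: Sequence[str], layout: ChannelLayout
) -> np.ndarray:
    norm = {_normalize_channel(n): i for i, n in enumerate(names)}
    rows = []
    for want in layout.names:
        key = _normalize_channel(want)
        if key not in norm:
            raise ChannelError(f"required channel {want!r} missing (file has {list(names)})")
        rows.append(norm[key])
    return data[rows]


def _write_fixture(rec: Recording, path: Path) -> None:
    header = {
        "subject_id": rec.subject_id,
        "condition": rec.condition,
        "fs": rec.fs,
        "channels": list(rec.layout.names),
        "n_samples": rec.n_samples,
    }
    blob = json.dumps(header).encode("utf-8")
    payload = zlib.compress(np.ascontiguousarray(rec.data, dtype="<f8").tobytes(), level=6)
    try:
        with open(path, "wb") as fh:
            fh.write(_FIXTURE_MAGIC)
            fh.write(struct.pack("<Q", len(blob)))
            fh.write(blob)
            fh.write(payload)
    except OSError as exc:
        raise FormatError(f"cannot write {path}: {exc}") from exc


def _read_fixture(path: Path) -> Recording:
    try:
        raw = Path(path).read_bytes()
    except OSError as exc:
        raise FormatError(f"cannot read {path}: {exc}") from exc
    if not raw.startswith(_FIXTURE_MAGIC):
        raise FormatError(f"{path} is not a fixture recording (bad magic)")
    off = len(_FIXTURE_MAGIC)
    (hlen,) = struct.unpack_from("<Q", raw, off)
    off += 8
    try:
        header = json.loads(raw[off : off + hlen].decode("utf-8"))
        data = np.frombuffer(zlib.decompress(raw[off + hlen :]), dtype="<f8")
        names = list(header["channels"])
        data = data.reshape(len(names), int(header["n_samples"]))
    except Exception as exc:
        raise FormatError(f"corrupt fixture file {path}: {exc}") from exc
    layout = ChannelLayout()
    data = _reorder_to_layout(np.array(data, dtype=np.float64), names, layout)
    return Recording(
        subject_id=str(header["subject_id"]),
        condition=str(header["condition"]),
        fs=float(header["fs"]),
        data=data,
        layout=layout,
    )


def _edf_field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValidationError(f"EDF header field {s!r} exceeds {width} chars")
    return s.ljust(width).encode("ascii")


def _write_edf(rec: Recording, path: Path) -> None:
    """Minimal 16-bit EDF writer: one 1-second data record per second.

    The sampling rate must be a positive integer and trailing samples
    short of a full second are dropped.
    """
    fs = int(round(rec.fs))
    if abs(fs - rec.fs) > 1e-9 or fs <= 0:
        raise ValidationError(f"EDF export needs an integer sampling rate, got {rec.fs}")
    n_records = rec.n_samples // fs
    if n_records == 0:
        raise ValidationError("recording shorter than one EDF data record (1 s)")
    data = rec.data[:, : n_records * fs]
    nch = rec.n_channels

    pmax = float(np.max(np.abs(data)))
    pmax = max(pmax, 1e-3)
    pmax = float(f"{pmax * 1.0000001:.6g}")  # 8-char-representable symmetric range
    pmin = -pmax
    dmin, dmax = -32768, 32767
    gain = (pmax - pmin) / (dmax - dmin)
    digital = np.clip(np.round((data - pmin) / gain) + dmin, dmin, dmax).astype("<i2")

    hdr = b""
    hdr += _edf_field("0", 8)
    hdr += _edf_field(rec.subject_id, 80)
    hdr += _edf_field(rec.condition, 80)
    hdr += _edf_field("01.01.00", 8)
    hdr += _edf_field("00.00.00", 8)
    hdr += _edf_field(256 * (nch + 1), 8)
    hdr += _edf_field("", 44)
    hdr += _edf_field(n_records, 8)
    hdr += _edf_field("1", 8)
    hdr += _edf_field(nch, 4)
    for name in rec.layout.names:
        hdr += _edf_field(name, 16)
    hdr += b"".join(_edf_field("", 80) for _ in range(nch))
    hdr += b"".join(_edf_field("uV", 8) for _ in range(nch))
    hdr += b"".join(_edf_field(f"{pmin:.6g}", 8) for _ in range(nch))
    hdr += b"".join(_edf_field(f"{pmax:.6g}", 8) for _ in range(nch))
    hdr += b"".join(_edf_field(dmin, 8) for _ in range(nch))
    hdr += b"".join(_edf_field(dmax, 8) for _ in range(nch))
    hdr += b"".join(_edf_field("", 80) for _ in range(nch))
    hdr += b"".join(_edf_field(fs, 8) for _ in range(nch))
    hdr += b"".join(_edf_field("", 32) for _ in range(nch))

    try:
        with open(path, "wb") as fh:
            fh.write(hdr)
            for r in range(n_records):
                fh.write(digital[:, r * fs : (r + 1) * fs].tobytes())
    except OSError as exc:
        raise FormatError(f"cannot write {path}: {exc}") from exc


def edf_quantization_step(path: str | Path) -> float:
    """Physical units per digital step declared in an EDF header."""
    with open(path, "rb") as fh:
        head = fh.read(256)
        nch = int(head[252:256].decode("ascii"))
        sig = fh.read(256 * nch)
    base = nch * (16 + 80 + 8)
    pmin = float(sig[base : base + 8].decode("ascii"))
    pmax = float(sig[base + 8 * nch : base + 8 * nch + 8].decode("ascii"))
    return (pmax - pmin) / 65535.0


def _read_edf(path: Path) -> Recording:
    import mne

    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:
        raise FormatError(f"cannot read EDF {path}: {exc}") from exc
    data = raw.get_data(units="uV")
    names = list(raw.ch_names)
    layout = ChannelLayout()
    data = _reorder_to_layout(np.asarray(data, dtype=np.float64), names, layout)
    # subject id / condition live in the two EDF header text fields we write
    with open(path, "rb") as fh:
        head = fh.read(168)
    subject_id = head[8:88].decode("ascii", "replace").strip() or path.stem
    condition = head[88:168].decode("ascii", "replace").strip().split()[-1] if head[88:168].strip() else "EC"
    if condition not in CONDITIONS:
        condition = "EC"
    return Recording(
        subject_id=subject_id,
        condition=condition,
        fs=float(raw.info["sfreq"]),
        data=data,
        layout=layout,
    )
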