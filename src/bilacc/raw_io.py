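"""Reading and writing raw wrist recordings and cohort metadata.

The raw file dialect follows the Empatica E4 ``ACC.csv`` export convention:
line 1 holds the recording start time (UTC epoch seconds), line 2 the nominal
sample rate in Hz, and every following line one ``x,y,z`` sample in signed
8-bit counts (64 counts = 1 g). E4 exports repeat the header value once per
column; both the single-value and the repeated form are accepted, and the
single-value form is written.

Counts are validated against the 8-bit contract, never clipped: silently
clipping saturated samples would bias the downstream magnitude statistic.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConsistencyError, FormatError, RangeError, TooShortError

ARM_LABELS = ("left", "right")
SESSIONS = ("T1", "T2")

#: Minimum number of raw samples: two full decimation windows.
MIN_SAMPLES = 192

COUNT_MIN, COUNT_MAX = -128, 127


@dataclass(frozen=True)
class RawRecording:
    """One arm's raw triaxial 8-bit count stream.

    The sample at 0-based index ``i`` occupies the half-open time interval
    ``[start_time + i/sample_rate_hz, start_time + (i+1)/sample_rate_hz)``.
    """

    arm_label: str
    start_time: float
    sample_rate_hz: float
    samples: np.ndarray  # (n, 3) integer counts

    def __post_init__(self) -> None:
        if self.arm_label not in ARM_LABELS:
            raise FormatError(f"arm_label must be one of {ARM_LABELS}, got {self.arm_label!r}")
        if not self.sample_rate_hz > 0:
            raise FormatError(f"sample rate must be positive, got {self.sample_rate_hz}")
        arr = np.asarray(self.samples)
        if arr.ndim != 2 or arr.shape[1] != 3:
            raise FormatError(f"samples must be (n, 3), got shape {arr.shape}")
        if len(arr) < MIN_SAMPLES:
            raise TooShortError(
                f"recording has {len(arr)} samples; need at least {MIN_SAMPLES} "
                "(two decimation windows)"
            )
        if arr.size and (arr.min() < COUNT_MIN or arr.max() > COUNT_MAX):
            raise RangeError(f"counts must lie in [{COUNT_MIN}, {COUNT_MAX}]")
        object.__setattr__(self, "samples", np.ascontiguousarray(arr, dtype=np.int16))

    def __len__(self) -> int:
        return len(self.samples)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RawRecording):
            return NotImplemented
        return (
            self.arm_label == other.arm_label
            and self.start_time == other.start_time
            and self.sample_rate_hz == other.sample_rate_hz
            and np.array_equal(self.samples, other.samples)
        )

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sample_rate_hz


@dataclass(frozen=True)
class ClinicalScores:
    """Affected-arm clinical scores: M-MAS sum (0-15) and MAL means (0-5)."""

    mas: int
    mal_aou: float
    mal_qom: float

    def __post_init__(self) -> None:
        if not (isinstance(self.mas, (int, np.integer)) and 0 <= self.mas <= 15):
            raise RangeError(f"mas must be an integer in 0..15, got {self.mas!r}")
        for name in ("mal_aou", "mal_qom"):
            v = getattr(self, name)
            if not (np.isfinite(v) and 0.0 <= v <= 5.0):
                raise RangeError(f"{name} must lie in [0, 5], got {v!r}")
        object.__setattr__(self, "mas", int(self.mas))


@dataclass(frozen=True)
class CohortRow:
    """One patient-session entry of the cohort metadata table."""

    patient_id: str
    affected_side: str
    session: str
    scores: ClinicalScores
    left_file: Path
    right_file: Path

    def __post_init__(self) -> None:
        if self.affected_side not in ARM_LABELS:
            raise FormatError(f"affected_side must be left/right, got {self.affected_side!r}")
        if self.session not in SESSIONS:
            raise FormatError(f"session must be T1 or T2, got {self.session!r}")


def _parse_header_value(line: str, what: str) -> float:
    # E4 exports repeat the header value per column; take the first field.
    first = line.strip().split(",")[0].strip()
    try:
        return float(first)
    except ValueError:
        raise FormatError(f"cannot parse {what} from header line {line!r}") from None


def read_raw_recording(path: str | Path, arm_label: str) -> RawRecording:
    """Read one E4-dialect CSV file into a :class:`RawRecording`.

    Raises
    ------
    FormatError
        Malformed header or body rows.
    RangeError
        Any count outside ``[-128, 127]``.
    TooShortError
        Fewer than 192 samples.
    """
    path = Path(path)
    with open(path, "r") as fh:
        header1 = fh.readline()
        header2 = fh.readline()
        if not header1 or not header2:
            raise FormatError(f"{path}: missing header lines")
        start_time = _parse_header_value(header1, "start time")
        rate = _parse_header_value(header2, "sample rate")
        if rate <= 0:
            raise FormatError(f"{path}: sample rate must be positive, got {rate}")
        body = fh.read()
    if not body.strip():
        raise TooShortError(f"{path}: no sample rows")
    try:
        frame = pd.read_csv(io.StringIO(body), header=None)
    except Exception as exc:  # pandas raises several parser error types
        raise FormatError(f"{path}: cannot parse sample rows: {exc}") from None
    if frame.shape[1] != 3:
        raise FormatError(f"{path}: expected 3 columns of counts, got {frame.shape[1]}")
    values = frame.to_numpy()
    if not np.all(np.isfinite(values)):
        raise FormatError(f"{path}: non-numeric sample values")
    rounded = np.rint(values)
    if not np.allclose(values, rounded, atol=1e-9):
        raise FormatError(f"{path}: counts must be integers")
    if rounded.min() < COUNT_MIN or rounded.max() > COUNT_MAX:
        raise RangeError(f"{path}: counts outside [{COUNT_MIN}, {COUNT_MAX}]")
    return RawRecording(
        arm_label=arm_label,
        start_time=start_time,
        sample_rate_hz=rate,
        samples=rounded.astype(np.int16),
    )


def write_raw_recording(rec: RawRecording, path: str | Path) -> Path:
    """Write a recording in the same dialect; round-trips bit-exactly."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"{rec.start_time!r}\n")
        fh.write(f"{rec.sample_rate_hz!r}\n")
        np.savetxt(fh, rec.samples, fmt="%d", delimiter=",")
    return path


_COHORT_COLUMNS = (
    "patient_id",
    "affected_side",
    "session",
    "mas",
    "mal_aou",
    "mal_qom",
    "left_file",
    "right_file",
)


def read_cohort_table(path: str | Path) -> list[CohortRow]:
    """Read and validate the cohort metadata CSV.

    File paths in ``left_file``/``right_file`` are resolved relative to the
    directory containing the table.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, dtype={"patient_id": str})
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse cohort table: {exc}") from None
    missing = [c for c in _COHORT_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")

    rows: list[CohortRow] = []
    seen: set[tuple[str, str]] = set()
    sides: dict[str, str] = {}
    base = path.parent
    for _, r in frame.iterrows():
        mas_val = r["mas"]
        if float(mas_val) != int(mas_val):
            raise RangeError(f"mas must be an integer, got {mas_val!r}")
        row = CohortRow(
            patient_id=str(r["patient_id"]),
            affected_side=str(r["affected_side"]),
            session=str(r["session"]),
            scores=ClinicalScores(int(mas_val), float(r["mal_aou"]), float(r["mal_qom"])),
            left_file=base / str(r["left_file"]),
            right_file=base / str(r["right_file"]),
        )
        key = (row.patient_id, row.session)
        if key in seen:
            raise ConsistencyError(f"duplicate entry for patient {key[0]} session {key[1]}")
        seen.add(key)
        prev = sides.setdefault(row.patient_id, row.affected_side)
        if prev != row.affected_side:
            raise ConsistencyError(
                f"patient {row.patient_id}: affected_side changes between sessions"
            )
        rows.append(row)
    return rows


def write_cohort_table(rows: Iterable[CohortRow], path: str | Path) -> Path:
    """Write cohort metadata; file paths are stored relative to the table."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    base = path.parent
    records = []
    for row in rows:
        records.append(
            {
                "patient_id": row.patient_id,
                "affected_side": row.affected_side,
                "session": row.session,
                "mas": row.scores.mas,
                "mal_aou": row.scores.mal_aou,
                "mal_qom": row.scores.mal_qom,
                "left_file": _relativize(row.left_file, base),
                "right_file": _relativize(row.right_file, base),
            }
        )
    pd.DataFrame.from_records(records, columns=list(_COHORT_COLUMNS)).to_csv(path, index=False)
    return path


def _relativize(p: Path, base: Path) -> str:
    try:
        return str(Path(p).relative_to(base))
    except ValueError:
        return str(p)
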