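"""Raw nanopore signal I/O: ASCII SLOW5 reading/writing and pA conversion.

Supports a minimal single-read-group ASCII SLOW5 dialect: ``#``-prefixed
header lines, a tab-separated column-header line, one tab-separated data
line per read with the raw signal as a comma-separated list of 16-bit ADC
counts. Per-read binary species labels live in a separate two-column
manifest (SLOW5 itself carries no labels).

ADC counts are converted to picoamperes with the standard ONT affine map

    pA = (range / digitisation) * (raw + offset)
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "RawRead",
    "Slow5FormatError",
    "Slow5RecordError",
    "read_slow5",
    "write_slow5",
    "to_picoamps",
    "read_label_manifest",
    "write_label_manifest",
]

INT16_MIN = -32768
INT16_MAX = 32767

#: canonical primary SLOW5 columns, in file order
SLOW5_COLUMNS = (
    "read_id",
    "read_group",
    "digitisation",
    "offset",
    "range",
    "sampling_rate",
    "len_raw_signal",
    "raw_signal",
)


class Slow5FormatError(ValueError):
    """File-level problem: missing header or missing required column."""


class Slow5RecordError(ValueError):
    """Record-level problem (carries the offending read_id in the message)."""


@dataclass
class RawRead:
    """One nanopore read: ADC samples plus digitiser metadata.

    Attributes
    ----------
    read_id : str
        Unique read identifier.
    raw_signal : np.ndarray
        int16 ADC counts, in acquisition order.
    digitisation : float
        Number of ADC quantisation levels spanning ``range_pA`` (> 0).
    offset : float
        ADC offset added to raw counts before scaling.
    range_pA : float
        Current range in picoamperes spanned by the digitiser (> 0).
    sampling_rate : float
        Acquisition frequency in Hz (> 0).
    label : int | None
        Optional binary species label (1 = target species, 0 = non-target).
    """

    read_id: str
    raw_signal: np.ndarray
    digitisation: float
    offset: float
    range_pA: float
    sampling_rate: float
    label: int | None = None

    def __post_init__(self) -> None:
        self.raw_signal = np.asarray(self.raw_signal)
        if self.raw_signal.ndim != 1:
            raise ValueError(f"read {self.read_id!r}: raw_signal must be 1-D")
        if self.raw_signal.size and (
            self.raw_signal.min() < INT16_MIN or self.raw_signal.max() > INT16_MAX
        ):
            raise ValueError(
                f"read {self.read_id!r}: raw_signal values outside int16 range"
            )
        self.raw_signal = self.raw_signal.astype(np.int16)
        for name in ("digitisation", "range_pA", "sampling_rate"):
            if not getattr(self, name) > 0:
                raise ValueError(f"read {self.read_id!r}: {name} must be > 0")
        if self.label is not None and self.label not in (0, 1):
            raise ValueError(f"read {self.read_id!r}: label must be 0 or 1")

    def __len__(self) -> int:
        return int(self.raw_signal.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RawRead):
            return NotImplemented
        return (
            self.read_id == other.read_id
            and np.array_equal(self.raw_signal, other.raw_signal)
            and self.digitisation == other.digitisation
            and self.offset == other.offset
            and self.range_pA == other.range_pA
            and self.sampling_rate == other.sampling_rate
            and self.label == other.label
        )


def to_picoamps(read: RawRead) -> np.ndarray:
    """Convert a read's ADC counts to picoamperes.

    Applies ``pA = (range / digitisation) * (raw + offset)`` elementwise;
    the map is affine with positive slope, hence order-preserving.
    """
    scale = read.range_pA / read.digitisation
    return scale * (read.raw_signal.astype(np.float64) + read.offset)


def write_slow5(reads: Iterable[RawRead], path: str | os.PathLike) -> None:
    """Write reads as ASCII SLOW5 (single read group). Lossless round trip.

    Validates every read (via the RawRead constructor invariants) before
    any output is written; an empty sequence yields a header-only file.
    """
    reads = list(reads)
    with open(path, "w") as fh:
        fh.write("#slow5_version\t2.0\n")
        fh.write("#num_read_groups\t1\n")
        fh.write("#" + "\t".join(SLOW5_COLUMNS) + "\n")
        for r in reads:
            sig = ",".join(str(int(v)) for v in r.raw_signal)
            fh.write(
                f"{r.read_id}\t0\t{r.digitisation!r}\t{r.offset!r}\t"
                f"{r.range_pA!r}\t{r.sampling_rate!r}\t{len(r)}\t{sig}\n"
            )


def read_slow5(path: str | os.PathLike) -> list[RawRead]:
    """Parse an ASCII SLOW5 file into a list of :class:`RawRead`.

    Raises
    ------
    Slow5FormatError
        If no column-header line is found or a required column is absent.
    Slow5RecordError
        If a record's declared ``len_raw_signal`` disagrees with the number
        of signal values listed, or a field fails to parse.
    """
    columns: list[str] | None = None
    reads: list[RawRead] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                fields = line[1:].split("\t")
                if "read_id" in fields:
                    columns = fields
                continue
            if columns is None:
                raise Slow5FormatError(
                    f"{path}: data line encountered before a column header line"
                )
            reads.append(_parse_record(line, columns))
    if columns is None:
        raise Slow5FormatError(f"{path}: no column header line found")
    missing = [c for c in SLOW5_COLUMNS if c not in columns]
    if missing:
        raise Slow5FormatError(f"{path}: missing required column(s): {missing}")
    return reads


def _parse_record(line: str, columns: list[str]) -> RawRead:
    parts = line.split("\t")
    if len(parts) != len(columns):
        raise Slow5RecordError(
            f"record {parts[0]!r}: expected {len(columns)} fields, got {len(parts)}"
        )
    rec = dict(zip(columns, parts))
    read_id = rec["read_id"]
    try:
        declared = int(rec["len_raw_signal"])
        signal = np.array(
            [int(v) for v in rec["raw_signal"].split(",")] if rec["raw_signal"] else [],
            dtype=np.int64,
        )
        read = RawRead(
            read_id=read_id,
            raw_signal=signal,
            digitisation=float(rec["digitisation"]),
            offset=float(rec["offset"]),
            range_pA=float(rec["range"]),
            sampling_rate=float(rec["sampling_rate"]),
        )
    except Slow5RecordError:
        raise
    except ValueError as exc:
        raise Slow5RecordError(f"record {read_id!r}: {exc}") from exc
    if declared != len(read):
        raise Slow5RecordError(
            f"record {read_id!r}: declared len_raw_signal {declared} "
            f"but {len(read)} samples listed"
        )
    return read


def write_label_manifest(
    labels: dict[str, int] | Sequence[tuple[str, int]], path: str | os.PathLike
) -> None:
    """Write a read_id -> binary label manifest (TSV, no header)."""
    items = labels.items() if isinstance(labels, dict) else labels
    with open(path, "w") as fh:
        for read_id, label in items:
            if label not in (0, 1):
                raise ValueError(f"label for {read_id!r} must be 0 or 1, got {label}")
            fh.write(f"{read_id}\t{label}\n")


def read_label_manifest(path: str | os.PathLike) -> dict[str, int]:
    """Read a two-column read_id <TAB> label manifest."""
    out: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2 or parts[1] not in ("0", "1"):
                raise ValueError(f"{path}:{lineno}: expected 'read_id<TAB>0|1'")
            out[parts[0]] = int(parts[1])
    return out


def attach_labels(reads: Sequence[RawRead], labels: dict[str, int]) -> None:
    """Set ``read.label`` in place from a manifest; unknown ids stay None."""
    for r in reads:
        if r.read_id in labels:
            r.label = labels[r.read_id]
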