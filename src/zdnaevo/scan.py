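"""Detection of Z-DNA-prone motifs and short tandem repeats (STRs).

Z-DNA is a left-handed helical conformation favoured by alternating
purine/pyrimidine tracts (classically (GC)n and (GT)n/(CA)n repeats).  The
scanner reports every maximal tract in which adjacent bases alternate
purine (A/G) vs pyrimidine (C/T), with A–T steps excluded by default (an
A–T or T–A dinucleotide alternates chemically but is not Z-prone under the
convention of the non-B DNA motif-search tools), above a minimum length.

STRs are perfect tandem repetitions of a short primitive unit (2–6 bp by
default).  A maximal tract is reported once, labelled by its primitive unit
in leftmost phase; a partial trailing copy extends the tract but does not
count towards the copy number.

Coordinates are 0-based half-open internally and 1-based inclusive in every
serialized output (the nBMST-style TSV and anything derived from it).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from Bio import SeqIO

from .errors import DataError

__all__ = [
    "MotifHit",
    "ScanParams",
    "scan_zdna",
    "scan_str",
    "scan_sequence",
    "read_fasta",
    "write_fasta",
    "write_motif_tsv",
    "read_motif_tsv",
]

_PURINES = frozenset("AG")
_ACGT = frozenset("ACGT")

# uint8 codes for the numpy fast path
_A, _C, _G, _T = (ord(c) for c in "ACGT")


@dataclass(frozen=True)
class MotifHit:
    """One detected motif tract, 1-based inclusive coordinates."""

    seq_id: str
    start: int
    stop: int
    motif_class: str  # "ZDNA" or "STR"
    sequence: str
    unit: str = ""  # STR only; primitive repeat unit in leftmost phase
    copies: int = 0  # STR only; number of complete unit copies

    @property
    def length(self) -> int:
        return self.stop - self.start + 1

    def __post_init__(self) -> None:
        if not self.seq_id:
            raise DataError("empty seq_id")
        if self.start < 1:
            raise DataError(f"start must be >= 1, got {self.start}")
        if self.stop < self.start:
            raise DataError(f"stop {self.stop} < start {self.start}")
        if len(self.sequence) != self.length:
            raise DataError(
                f"sequence length {len(self.sequence)} != stop-start+1 = {self.length}"
            )
        if self.motif_class not in ("ZDNA", "STR"):
            raise DataError(f"unknown motif_class {self.motif_class!r}")


@dataclass(frozen=True)
class ScanParams:
    """Scanner thresholds.

    Defaults follow the published non-B motif-search conventions: Z-DNA
    tracts of at least 10 nt with A–T steps disallowed; STR units of 2-6 bp
    with at least 3 full copies spanning at least 10 nt.  Softmasked
    (lowercase) bases are scanned by default.
    """

    zdna_min_len: int = 10
    zdna_allow_at_steps: bool = False
    str_unit_min: int = 2
    str_unit_max: int = 6
    str_min_copies: int = 3
    str_min_len: int = 10
    include_softmasked: bool = True

    def __post_init__(self) -> None:
        if self.zdna_min_len < 2:
            raise DataError("zdna_min_len must be >= 2")
        if not (1 <= self.str_unit_min <= self.str_unit_max <= 9):
            raise DataError("require 1 <= str_unit_min <= str_unit_max <= 9")
        if self.str_min_copies < 2:
            raise DataError("str_min_copies must be >= 2")


def _prepare(seq: str, params: ScanParams) -> str:
    """Resolve case handling: return an uppercase string in which any base
    that must not be scanned is replaced by 'N' (which terminates tracts)."""
    if params.include_softmasked:
        return seq.upper()
    # lowercase = softmasked = off limits
    return "".join(c if c in _ACGT else "N" for c in seq)


# ---------------------------------------------------------------------------
# Z-DNA scan
# ---------------------------------------------------------------------------

def _zdna_step_ok(a: str, b: str, allow_at: bool) -> bool:
    if a not in _ACGT or b not in _ACGT:
        return False
    if (a in _PURINES) == (b in _PURINES):
        return False
    if not allow_at and {a, b} == {"A", "T"}:
        return False
    return True


def _zdna_intervals_small(s: str, params: ScanParams) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    n = len(s)
    i = 0
    while i < n:
        if s[i] not in _ACGT:
            i += 1
            continue
        j = i
        while j + 1 < n and _zdna_step_ok(s[j], s[j + 1], params.zdna_allow_at_steps):
            j += 1
        if j - i + 1 >= params.zdna_min_len:
            out.append((i, j + 1))
        i = j + 1
    return out


def _zdna_intervals_numpy(s: str, params: ScanParams) -> list[tuple[int, int]]:
    arr = np.frombuffer(s.encode("ascii"), dtype=np.uint8)
    valid = (arr == _A) | (arr == _C) | (arr == _G) | (arr == _T)
    purine = (arr == _A) | (arr == _G)
    a, b = arr[:-1], arr[1:]
    step = valid[:-1] & valid[1:] & (purine[:-1] != purine[1:])
    if not params.zdna_allow_at_steps:
        at = ((a == _A) & (b == _T)) | ((a == _T) & (b == _A))
        step &= ~at
    return _runs_to_intervals(step, tail=1, min_len=params.zdna_min_len)


def _runs_to_intervals(mask: np.ndarray, tail: int, min_len: int) -> list[tuple[int, int]]:
    """Maximal runs of True in ``mask``; run [a..b] maps to interval [a, b+1+tail)."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [idx.size - 1]))
    out = []
    for a, b in zip(idx[starts], idx[ends]):
        if b - a + 1 + tail >= min_len:
            out.append((int(a), int(b) + 1 + tail))
    return out


def scan_zdna(seq: str, seq_id: str, params: ScanParams | None = None) -> list[MotifHit]:
    """Return all maximal Z-DNA-prone tracts in ``seq``, sorted by start.

    A tract is maximal when it cannot be extended in either direction while
    every adjacent pair still alternates purine/pyrimidine (A-T steps and
    non-ACGT symbols break tracts).
    """
    if not seq_id:
        raise DataError("empty seq_id")
    params = params or ScanParams()
    if not seq:
        return []
    s = _prepare(seq, params)
    if len(s) < 256:
        ivals = _zdna_intervals_small(s, params)
    else:
        ivals = _zdna_intervals_numpy(s, params)
    return [
        MotifHit(seq_id=seq_id, start=i + 1, stop=j, motif_class="ZDNA",
                 sequence=seq[i:j])
        for i, j in ivals
    ]


# ---------------------------------------------------------------------------
# STR scan
# ---------------------------------------------------------------------------

def _is_primitive(unit: str) -> bool:
    p = len(unit)
    for d in range(1, p):
        if p % d == 0 and unit == unit[:d] * (p // d):
            return False
    return True


def _str_hits_period(s: str, p: int, params: ScanParams) -> list[tuple[int, int, int]]:
    """Candidate maximal period-``p`` tracts as (start, end, copies), 0-based half-open."""
    n = len(s)
    if n < p + 1:
        return []
    out: list[tuple[int, int, int]] = []
    if n >= 256:
        arr = np.frombuffer(s.encode("ascii"), dtype=np.uint8)
        valid = (arr == _A) | (arr == _C) | (arr == _G) | (arr == _T)
        match = valid[:-p] & valid[p:] & (arr[:-p] == arr[p:])
        for a, e in _runs_to_intervals(match, tail=p, min_len=params.str_min_len):
            copies = (e - a) // p
            if copies >= params.str_min_copies and _is_primitive(s[a:a + p]):
                out.append((a, e, copies))
        return out
    i = 0
    while i < n - p:
        if s[i] in _ACGT and s[i] == s[i + p]:
            j = i
            while j + 1 < n - p and s[j + 1] in _ACGT and s[j + 1] == s[j + 1 + p]:
                j += 1
            a, e = i, j + 1 + p
            copies = (e - a) // p
            if (e - a >= params.str_min_len and copies >= params.str_min_copies
                    and _is_primitive(s[a:a + p])):
                out.append((a, e, copies))
            i = j + 2
        else:
            i += 1
    return out


def scan_str(seq: str, seq_id: str, params: ScanParams | None = None) -> list[MotifHit]:
    """Return all maximal perfect tandem-repeat tracts, sorted by start.

    Each tract appears once, labelled by its primitive unit in leftmost
    phase; a trailing partial copy extends the tract but not the copy count.
    """
    if not seq_id:
        raise DataError("empty seq_id")
    params = params or ScanParams()
    if not seq:
        return []
    s = _prepare(seq, params)
    hits: list[MotifHit] = []
    for p in range(params.str_unit_min, params.str_unit_max + 1):
        for a, e, copies in _str_hits_period(s, p, params):
            hits.append(
                MotifHit(seq_id=seq_id, start=a + 1, stop=e,
                         motif_class="STR", sequence=seq[a:e],
                         unit=s[a:a + p], copies=copies)
            )
    hits.sort(key=lambda h: (h.start, h.stop, h.unit))
    return hits


def scan_sequence(seq: str, seq_id: str, params: ScanParams | None = None
                  ) -> tuple[list[MotifHit], list[MotifHit]]:
    """Run both scans; Z-DNA and STR detections are fully independent."""
    return scan_zdna(seq, seq_id, params), scan_str(seq, seq_id, params)


# ---------------------------------------------------------------------------
# FASTA helpers
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (record id, sequence) from a FASTA file, gzip transparent."""
    path = Path(path)
    if path.suffix == ".gz":
        with gzip.open(path, "rt") as fh:
            yield from ((r.id, str(r.seq)) for r in SeqIO.parse(fh, "fasta"))
    else:
        with open(path) as fh:
            yield from ((r.id, str(r.seq)) for r in SeqIO.parse(fh, "fasta"))


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path,
                width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# Motif TSV serialization (nBMST-style layout)
# ---------------------------------------------------------------------------

_TSV_COLUMNS = ("Sequence_name", "Source", "Type", "Start", "Stop",
                "Length", "Unit", "Copies", "Sequence")
_SOURCE = "zdnaevo"


def write_motif_tsv(hits: Iterable[MotifHit], path: str | Path) -> None:
    """Serialize hits to a tab-separated file, 1-based inclusive coordinates."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(_TSV_COLUMNS) + "\n")
        for h in hits:
            fh.write("\t".join((
                h.seq_id, _SOURCE, h.motif_class, str(h.start), str(h.stop),
                str(h.length), h.unit or ".", str(h.copies), h.sequence,
            )) + "\n")


def read_motif_tsv(path: str | Path) -> list[MotifHit]:
    """Parse a motif TSV written by :func:`write_motif_tsv`.

    Raises :class:`DataError` naming the offending line on malformed input
    (wrong column count, non-integer coordinates, Stop < Start, length
    mismatch).
    """
    hits: list[MotifHit] = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header:
            raise DataError(f"{path}: empty file")
        if tuple(header.rstrip("\n").split("\t")) != _TSV_COLUMNS:
            raise DataError(f"{path}: line 1: unexpected header")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(_TSV_COLUMNS):
                raise DataError(
                    f"{path}: line {lineno}: expected {len(_TSV_COLUMNS)} "
                    f"columns, got {len(parts)}")
            seq_id, _src, mclass, start, stop, length, unit, copies, seq = parts
            try:
                start_i, stop_i, len_i, copies_i = (
                    int(start), int(stop), int(length), int(copies))
            except ValueError as exc:
                raise DataError(f"{path}: line {lineno}: {exc}") from None
            try:
                hit = MotifHit(seq_id=seq_id, start=start_i, stop=stop_i,
                               motif_class=mclass, sequence=seq,
                               unit="" if unit == "." else unit,
                               copies=copies_i)
            except DataError as exc:
                raise DataError(f"{path}: line {lineno}: {exc}") from None
            if len_i != hit.length:
                raise DataError(
                    f"{path}: line {lineno}: Length column {len_i} "
                    f"inconsistent with coordinates")
            hits.append(hit)
    return hits
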