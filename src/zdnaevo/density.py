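"""Per-species motif densities (motifs per Mb) and the multi-species table.

Density is motif count divided by genome size, reported per megabase.
Genome size is the total assembly length including gap (N) runs by default;
pass ``ungapped=True`` to exclude non-ACGT symbols from the denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd

from .errors import DataError
from .scan import read_fasta

__all__ = [
    "SpeciesGenomeSummary",
    "genome_size",
    "motif_density",
    "build_density_table",
    "read_density_table",
]

DENSITY_COLUMNS = ("species", "genome_size_bp", "zdna_count", "str_count",
                   "zdna_density_per_mb", "str_density_per_mb")


@dataclass(frozen=True)
class SpeciesGenomeSummary:
    species: str
    genome_size_bp: int
    zdna_count: int
    str_count: int

    def __post_init__(self) -> None:
        if self.genome_size_bp <= 0:
            raise DataError("genome_size_bp must be > 0")
        if self.zdna_count < 0 or self.str_count < 0:
            raise DataError("motif counts must be >= 0")

    @property
    def zdna_density(self) -> float:
        return motif_density(self.zdna_count, self.genome_size_bp)

    @property
    def str_density(self) -> float:
        return motif_density(self.str_count, self.genome_size_bp)


def genome_size(fasta: str | Path, ungapped: bool = False) -> int:
    """Total assembly length in bp summed over all FASTA records.

    N and softmasked (lowercase) symbols count by default; with
    ``ungapped=True`` only A/C/G/T (either case) are counted.
    """
    total = 0
    n_records = 0
    for _name, seq in read_fasta(fasta):
        n_records += 1
        if ungapped:
            total += sum(seq.upper().count(c) for c in "ACGT")
        else:
            total += len(seq)
    if n_records == 0:
        raise DataError(f"{fasta}: no FASTA records")
    if total == 0:
        raise DataError(f"{fasta}: zero-length assembly")
    return total


def motif_density(count: int, genome_size_bp: int) -> float:
    """Motifs per megabase: count * 1e6 / genome_size_bp."""
    if genome_size_bp <= 0:
        raise DataError("genome_size_bp must be > 0")
    if count < 0:
        raise DataError("count must be >= 0")
    return count * 1_000_000 / genome_size_bp


def build_density_table(summaries: Iterable[SpeciesGenomeSummary]) -> pd.DataFrame:
    """One row per species, fixed column order; duplicate species are rejected."""
    rows = list(summaries)
    labels = [s.species for s in rows]
    dupes = sorted({x for x in labels if labels.count(x) > 1})
    if dupes:
        raise DataError(f"duplicate species labels: {', '.join(dupes)}")
    return pd.DataFrame(
        [(s.species, s.genome_size_bp, s.zdna_count, s.str_count,
          s.zdna_density, s.str_density) for s in rows],
        columns=list(DENSITY_COLUMNS),
    )


def read_density_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in DENSITY_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing columns {missing}")
    return df
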