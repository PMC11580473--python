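"""Positional analysis of Z-DNA motifs upstream of start codons.

A gene's upstream window is the 10 kb (configurable) region 5' of the first
base of its start codon.  A motif is assigned to a gene when its anchor
coordinate — the motif end nearest the gene in transcription direction
under the default "oriented" convention, or the literal Stop column under
the "genomic" convention — falls inside the window.  Distances from the
start codon are binned per kb, giving a species x region count matrix on
which normality (Lilliefors) and rank tests (Friedman, Nemenyi all-pairs)
are run, and per-gene counts from which the top-5% Z-DNA-rich gene list is
drawn.
"""

from __future__ import annotations

import functools
from bisect import bisect_left, bisect_right
from collections import Counter, defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError
from .scan import MotifHit

__all__ = [
    "GeneRecord",
    "UpstreamAssignment",
    "extract_start_codons",
    "assign_upstream_motifs",
    "positional_profile",
    "build_region_matrix",
    "per_gene_counts",
    "lilliefors_test",
    "friedman_test",
    "nemenyi_allpairs",
    "top_percent_genes",
    "DIALECTS",
]

DIALECTS = ("augustus", "ncbiRefSeq", "xenoRefGene")


@dataclass(frozen=True)
class GeneRecord:
    """A gene anchored at the first base of its start codon (1-based)."""

    gene_id: str
    seq_id: str
    strand: str
    start_codon_pos: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise DataError(f"strand must be + or -, got {self.strand!r}")
        if self.start_codon_pos < 1:
            raise DataError("start_codon_pos must be >= 1")


@dataclass(frozen=True)
class UpstreamAssignment:
    gene_id: str
    motif: MotifHit
    distance_bp: int
    bin_index: int


# ---------------------------------------------------------------------------
# Annotation parsing
# ---------------------------------------------------------------------------

def _gene_id_of(dialect: str, attrs: Mapping[str, Sequence[str]]) -> str | None:
    tx = attrs.get("transcript_id", [None])[0]
    gene = attrs.get("gene_id", [None])[0]
    if dialect == "augustus":
        # Augustus transcript ids look like g17.t1; the gene is g17.  UCSC
        # exports sometimes carry only gene_id in the same style.
        name = tx or gene
        if name is None:
            return None
        base, dot, suffix = name.rpartition(".")
        if dot and suffix.startswith("t") and suffix[1:].isdigit():
            return base
        return name
    # ncbiRefSeq / xenoRefGene: gene_id is the gene symbol (falls back to
    # the transcript accession when absent).
    return gene or tx


def extract_start_codons(annotation: str | Path, dialect: str) -> list[GeneRecord]:
    """One :class:`GeneRecord` per gene from a UCSC-style GTF/GFF export.

    ``start_codon`` features are used when present; otherwise the 5' end of
    the 5'-most CDS stands in.  For genes with several transcripts the
    5'-most start codon (smallest coordinate on +, largest on -) wins.
    """
    if dialect not in DIALECTS:
        raise DataError(
            f"unknown annotation dialect {dialect!r}; supported: "
            + ", ".join(DIALECTS))
    import gffutils

    db = gffutils.create_db(
        str(annotation), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True, disable_infer_transcripts=True)

    # candidate position per gene: (seq_id, strand) -> positions
    candidates: dict[tuple[str, str, str], list[int]] = defaultdict(list)
    seen_start_codon: set[str] = set()

    for feat in db.features_of_type("start_codon"):
        gid = _gene_id_of(dialect, feat.attributes)
        if gid is None:
            continue
        pos = feat.start if feat.strand == "+" else feat.end
        candidates[(gid, feat.seqid, feat.strand)].append(pos)
        seen_start_codon.add(gid)

    for feat in db.features_of_type("CDS"):
        gid = _gene_id_of(dialect, feat.attributes)
        if gid is None or gid in seen_start_codon:
            continue
        pos = feat.start if feat.strand == "+" else feat.end
        candidates[(gid, feat.seqid, feat.strand)].append(pos)

    if not candidates:
        raise DataError(f"{annotation}: no gene-bearing features "
                        "(no start_codon or CDS records)")

    records = []
    for (gid, seqid, strand), positions in candidates.items():
        pos = min(positions) if strand == "+" else max(positions)
        records.append(GeneRecord(gene_id=gid, seq_id=seqid, strand=strand,
                                  start_codon_pos=pos))
    records.sort(key=lambda g: (g.seq_id, g.start_codon_pos, g.gene_id))
    return records


# ---------------------------------------------------------------------------
# Window assignment
# ---------------------------------------------------------------------------

def assign_upstream_motifs(
    genes: Iterable[GeneRecord],
    hits: Iterable[MotifHit],
    window_bp: int = 10_000,
    bin_bp: int = 1_000,
    convention: str = "oriented",
) -> list[UpstreamAssignment]:
    """Assign each motif to every gene whose upstream window contains its anchor.

    On + strand the window is [pos-window_bp, pos-1] and the anchor is the
    motif stop.  On - strand the window is [pos+1, pos+window_bp]; the
    anchor is the motif start under the default oriented convention (the
    end nearest the gene in transcription direction) or the motif stop
    under the literal ``genomic`` convention.  distance = number of bases
    between anchor and start codon (1..window_bp); bin = ceil(distance/bin_bp).
    """
    if window_bp <= 0 or bin_bp <= 0 or window_bp % bin_bp != 0:
        raise DataError("window_bp must be a positive multiple of bin_bp")
    if convention not in ("oriented", "genomic"):
        raise DataError(f"unknown stop-site convention {convention!r}")

    by_seq: dict[str, list[MotifHit]] = defaultdict(list)
    for h in hits:
        by_seq[h.seq_id].append(h)
    anchors: dict[str, tuple[list[int], list[MotifHit]]] = {}
    minus_key = "start" if convention == "oriented" else "stop"
    for seq_id, hs in by_seq.items():
        plus = sorted(hs, key=lambda h: h.stop)
        minus = sorted(hs, key=lambda h: getattr(h, minus_key))
        anchors[seq_id] = (
            ([h.stop for h in plus], plus),
            ([getattr(h, minus_key) for h in minus], minus),
        )

    out: list[UpstreamAssignment] = []
    for g in genes:
        if g.seq_id not in anchors:
            continue
        (plus_pos, plus_hits), (minus_pos, minus_hits) = anchors[g.seq_id]
        if g.strand == "+":
            lo, hi = g.start_codon_pos - window_bp, g.start_codon_pos - 1
            pos_list, hit_list = plus_pos, plus_hits
        else:
            lo, hi = g.start_codon_pos + 1, g.start_codon_pos + window_bp
            pos_list, hit_list = minus_pos, minus_hits
        if hi < 1:
            continue
        lo = max(lo, 1)  # clipped at contig start
        i0 = bisect_left(pos_list, lo)
        i1 = bisect_right(pos_list, hi)
        for idx in range(i0, i1):
            anchor = pos_list[idx]
            distance = (g.start_codon_pos - anchor if g.strand == "+"
                        else anchor - g.start_codon_pos)
            out.append(UpstreamAssignment(
                gene_id=g.gene_id, motif=hit_list[idx],
                distance_bp=distance,
                bin_index=-(-distance // bin_bp)))
    return out


def positional_profile(
    assignments: Iterable[UpstreamAssignment],
    n_bins: int = 10,
) -> tuple[np.ndarray, Counter]:
    """Counts per distance bin (one species) plus per-position counts.

    Returns (length-``n_bins`` integer vector, Counter of distance -> count).
    Bin totals sum to the number of assignments.
    """
    bins = np.zeros(n_bins, dtype=int)
    positions: Counter = Counter()
    for a in assignments:
        if not (1 <= a.bin_index <= n_bins):
            raise DataError(
                f"assignment bin {a.bin_index} outside 1..{n_bins}")
        bins[a.bin_index - 1] += 1
        positions[a.distance_bp] += 1
    return bins, positions


def build_region_matrix(rows: Mapping[str, np.ndarray]) -> pd.DataFrame:
    """Species x distance-bin matrix from per-species bin vectors."""
    if not rows:
        raise DataError("no species rows")
    k = {len(v) for v in rows.values()}
    if len(k) != 1:
        raise DataError("inconsistent bin counts across species")
    n_bins = k.pop()
    df = pd.DataFrame.from_dict(
        {sp: np.asarray(v, dtype=int) for sp, v in rows.items()},
        orient="index", columns=[f"bin_{i}" for i in range(1, n_bins + 1)])
    df.index.name = "species"
    return df


def per_gene_counts(genes: Iterable[GeneRecord],
                    assignments: Iterable[UpstreamAssignment]) -> pd.Series:
    """Number of assigned motifs per gene (genes with none count 0)."""
    counts = Counter(a.gene_id for a in assignments)
    idx = [g.gene_id for g in genes]
    return pd.Series([counts.get(g, 0) for g in idx], index=idx, name="zdna_count")


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

@functools.lru_cache(maxsize=32)
def _lilliefors_null(n: int, reps: int, seed: int) -> np.ndarray:
    """Sorted Monte-Carlo null distribution of the Lilliefors D at size n."""
    rng = np.random.default_rng(seed)
    sample = rng.standard_normal((reps, n))
    return np.sort(_lilliefors_d(sample))


def _lilliefors_d(x: np.ndarray) -> np.ndarray:
    """Row-wise D = sup |F_n - Phi((x-mean)/sd)| for a 2-D array."""
    x = np.sort(x, axis=-1)
    n = x.shape[-1]
    mu = x.mean(axis=-1, keepdims=True)
    sd = x.std(axis=-1, ddof=1, keepdims=True)
    cdf = stats.norm.cdf((x - mu) / sd)
    i = np.arange(1, n + 1)
    d_plus = (i / n - cdf).max(axis=-1)
    d_minus = (cdf - (i - 1) / n).max(axis=-1)
    return np.maximum(d_plus, d_minus)


def lilliefors_test(x: Sequence[float], mc_reps: int = 10_000,
                    seed: int = 0) -> tuple[float, float]:
    """Lilliefors normality test (KS with estimated mean and variance).

    The p-value comes from a seeded Monte-Carlo reference distribution of D
    under normality at the same sample size, so it is exact up to
    simulation error rather than relying on asymptotic tables.
    """
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1 or arr.size < 4:
        raise DataError("need a 1-D sample with n >= 4")
    if np.ptp(arr) == 0:
        raise DataError("constant sample: Lilliefors statistic undefined")
    d = float(_lilliefors_d(arr[None, :])[0])
    null = _lilliefors_null(arr.size, mc_reps, seed)
    # (1 + exceedances) / (reps + 1): valid Monte-Carlo p-value
    p = (1 + null.size - np.searchsorted(null, d, side="left")) / (null.size + 1)
    return d, float(p)


def _friedman_statistic(m: np.ndarray) -> float:
    n, k = m.shape
    ranks = np.apply_along_axis(stats.rankdata, 1, m)
    rank_sums = ranks.sum(axis=0)
    chi = 12.0 / (n * k * (k + 1)) * np.sum(rank_sums ** 2) - 3.0 * n * (k + 1)
    tie_sum = 0.0
    for row in m:
        _, counts = np.unique(row, return_counts=True)
        tie_sum += float(np.sum(counts ** 3 - counts))
    correction = 1.0 - tie_sum / (n * k * (k * k - 1))
    if correction <= 0:
        return 0.0  # every block fully tied
    return float(chi / correction)


def friedman_test(matrix: np.ndarray, p_method: str = "chisq"
                  ) -> tuple[float, int, float]:
    """Friedman rank test across k related treatments in n blocks.

    Within-block average ranks with ties; the statistic is the classical
    rank-sum chi-square divided by the tie-correction factor
    1 - sum(t^3 - t) / (n k (k^2 - 1)); df = k - 1.  The p-value is the
    upper-tail chi-square probability by default; ``p_method="exact"``
    enumerates all (k!)^n within-block orderings, which is feasible only
    for very small matrices and is exact in the permutation sense.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2:
        raise DataError("matrix must be 2-D (blocks x treatments)")
    n, k = m.shape
    if n < 2 or k < 2:
        raise DataError("need at least 2 blocks and 2 treatments")
    if not np.isfinite(m).all():
        raise DataError("incomplete matrix: non-finite cells")
    chi = _friedman_statistic(m)
    df = k - 1
    if p_method == "chisq":
        return chi, df, float(stats.chi2.sf(chi, df)) if chi > 0 else 1.0
    if p_method != "exact":
        raise DataError(f"unknown p_method {p_method!r}")
    import itertools as it
    import math
    total_orderings = math.factorial(k) ** n
    if total_orderings > 2_000_000:
        raise DataError("exact permutation p infeasible for this size")
    perms = list(it.permutations(range(k)))
    exceed = 0
    for combo in it.product(perms, repeat=n):
        pm = np.stack([m[b, list(combo[b])] for b in range(n)])
        if _friedman_statistic(pm) >= chi - 1e-12:
            exceed += 1
    return chi, df, exceed / total_orderings


def nemenyi_allpairs(matrix: np.ndarray) -> pd.DataFrame:
    """Nemenyi all-pairs post-hoc p-values after a Friedman test.

    For treatments i, j with mean ranks Rbar the observed statistic is
    q = |Rbar_i - Rbar_j| / sqrt(k (k+1) / (12 n)) referred to the
    studentized range distribution with k groups and infinite df.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2:
        raise DataError("matrix must be 2-D (blocks x treatments)")
    n, k = m.shape
    if n < 2 or k < 2:
        raise DataError("need at least 2 blocks and 2 treatments")
    if not np.isfinite(m).all():
        raise DataError("incomplete matrix: non-finite cells")
    ranks = np.apply_along_axis(stats.rankdata, 1, m)
    mean_ranks = ranks.mean(axis=0)
    se = np.sqrt(k * (k + 1) / (12.0 * n))
    q = np.abs(mean_ranks[:, None] - mean_ranks[None, :]) / se
    p = stats.studentized_range.sf(q, k, np.inf)
    p = np.minimum(1.0, np.where(np.isnan(p), 1.0, p))
    np.fill_diagonal(p, 1.0)
    cols = [f"bin_{i}" for i in range(1, k + 1)]
    return pd.DataFrame(p, index=cols, columns=cols)


def top_percent_genes(counts: Mapping[str, int] | pd.Series,
                      q: float = 0.05) -> tuple[list[str], int]:
    """Genes in the top ``q`` fraction by motif count, tie-inclusive.

    With G genes, m = ceil(q * G); the threshold c is the count of the m-th
    gene in descending order, and every gene with count >= c is returned
    (a superset of the strict top m).  Returns (gene ids sorted by count
    descending then id, threshold).
    """
    if not (0 < q < 1):
        raise DataError("q must be in (0, 1)")
    items = list(counts.items())
    if not items:
        raise DataError("need at least one gene")
    items.sort(key=lambda kv: (-kv[1], kv[0]))
    m = int(np.ceil(q * len(items)))
    threshold = items[m - 1][1]
    selected = [g for g, c in items if c >= threshold]
    return selected, int(threshold)
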