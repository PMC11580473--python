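"""Synthetic fixtures with known ground truth for every pipeline stage.

Generators emit standard formats (FASTA, GTF, newick, CSV) together with
machine-readable truth records, and are bit-reproducible from their seed:

* genomes whose background is scrubbed of scanner-valid motifs so that the
  planted motif set IS the expected scanner output ("planted-only" mode);
* annotations whose upstream windows contain a chosen number of motifs in
  chosen distance bins;
* ultrametric pure-birth (Yule) trees;
* continuous traits drawn from the exact model covariances used by the
  comparative machinery (BM/OU/EB/lambda), optionally with a linear
  regression structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import DataError
from .phylo import Phylogeny, model_covariance
from .promoter import GeneRecord
from .scan import MotifHit, ScanParams, scan_str, scan_zdna

__all__ = [
    "PlantSpec",
    "SimConfig",
    "random_zdna_payload",
    "random_str_payload",
    "sim_genome",
    "sim_annotation",
    "sim_promoter_dataset",
    "sim_yule_tree",
    "sim_trait",
    "sim_regression_dataset",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_PLANTED_ONLY_MAX_CONTIG = 5_000_000
_MAX_REPAIR_ITER = 200


@dataclass(frozen=True)
class PlantSpec:
    """One motif to plant: contig, 1-based position, class and payload."""

    contig: str
    position: int
    motif_class: str  # "ZDNA" or "STR"
    payload: str
    unit: str = ""
    copies: int = 0

    def __post_init__(self) -> None:
        if self.position < 1:
            raise DataError("plant position must be >= 1")
        if self.motif_class not in ("ZDNA", "STR"):
            raise DataError(f"unknown motif class {self.motif_class!r}")

    @property
    def end(self) -> int:  # 1-based inclusive
        return self.position + len(self.payload) - 1

    def truth_hits(self, params: ScanParams) -> list[MotifHit]:
        """Expected scanner output for this plant (both classes: a (TG)n
        tract, for instance, is a Z-DNA motif and an STR)."""
        out = []
        for h in scan_zdna(self.payload, self.contig, params):
            out.append(MotifHit(seq_id=self.contig,
                                start=self.position + h.start - 1,
                                stop=self.position + h.stop - 1,
                                motif_class="ZDNA",
                                sequence=h.sequence))
        for h in scan_str(self.payload, self.contig, params):
            out.append(MotifHit(seq_id=self.contig,
                                start=self.position + h.start - 1,
                                stop=self.position + h.stop - 1,
                                motif_class="STR", sequence=h.sequence,
                                unit=h.unit, copies=h.copies))
        if not out:
            raise DataError(
                f"plant payload {self.payload!r} yields no scanner hit "
                "under the active parameters")
        return out


@dataclass
class SimConfig:
    """Study conditions for a full synthetic bundle.

    Defaults: 12 species with 0.5-Mb single-contig genomes at 45% GC
    (avian-like), 25 planted Z-DNA and 40 planted STR tracts per genome,
    20 annotated genes per genome, a unit-rate Yule tree over the species,
    and BM traits with sigma^2 = 1.
    """

    seed: int = 0
    n_species: int = 12
    contig_length_bp: int = 500_000
    gc: float = 0.45
    zdna_plants: int = 25
    str_plants: int = 40
    n_genes: int = 20
    birth_rate: float = 1.0
    trait_model: str = "BM"
    trait_sigma2: float = 1.0
    trait_shape: float | None = None
    beta0: float = 0.0
    beta1: float = 0.5

    def __post_init__(self) -> None:
        if self.seed is None:
            raise DataError("seed is mandatory")
        for name in ("contig_length_bp", "n_species", "birth_rate",
                     "trait_sigma2"):
            if getattr(self, name) < 0 or (
                    name in ("contig_length_bp", "n_species", "birth_rate")
                    and getattr(self, name) <= 0):
                raise DataError(f"{name} must be positive")
        if not (0.0 < self.gc < 1.0):
            raise DataError("gc must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Payload generators
# ---------------------------------------------------------------------------

def random_zdna_payload(rng: np.random.Generator, length: int | None = None,
                        params: ScanParams | None = None) -> str:
    """A random alternating purine/pyrimidine tract without A-T steps."""
    params = params or ScanParams()
    if length is None:
        length = int(rng.integers(params.zdna_min_len, 41))
    if length < params.zdna_min_len:
        raise DataError("payload shorter than zdna_min_len")
    out = [rng.choice(list("ACGT"))]
    for _ in range(length - 1):
        prev = out[-1]
        if prev in "AG":  # purine -> pyrimidine, no T after A
            choices = "C" if prev == "A" else "CT"
        else:  # pyrimidine -> purine, no A after T
            choices = "G" if prev == "T" else "AG"
        out.append(choices[int(rng.integers(len(choices)))])
    return "".join(out)


def random_str_payload(rng: np.random.Generator,
                       params: ScanParams | None = None) -> tuple[str, str, int]:
    """A random perfect tandem tract; returns (payload, unit, copies)."""
    params = params or ScanParams()
    while True:
        p = int(rng.integers(params.str_unit_min, params.str_unit_max + 1))
        unit = "".join(rng.choice(list("ACGT")) for _ in range(p))
        if all(unit != unit[:d] * (p // d)
               for d in range(1, p) if p % d == 0):
            break
    min_copies = max(params.str_min_copies, -(-params.str_min_len // p))
    copies = int(rng.integers(min_copies, min_copies + 6))
    return unit * copies, unit, copies


# ---------------------------------------------------------------------------
# Genome simulation
# ---------------------------------------------------------------------------

def _random_background(rng: np.random.Generator, length: int, gc: float
                       ) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=length, p=p)


def _scan_all(seq: str, contig: str, params: ScanParams) -> list[MotifHit]:
    return scan_zdna(seq, contig, params) + scan_str(seq, contig, params)


def _repair(arr: np.ndarray, contig: str, params: ScanParams,
            rng: np.random.Generator,
            truth: frozenset[tuple], protected: np.ndarray) -> np.ndarray:
    """Mutate unprotected bases until the scan equals the truth set exactly."""
    for _ in range(_MAX_REPAIR_ITER):
        seq = arr.tobytes().decode("ascii")
        found = {(h.motif_class, h.start, h.stop, h.unit)
                 for h in _scan_all(seq, contig, params)}
        extra = found - truth
        missing = truth - found
        if not extra and not missing:
            return arr
        if missing and not extra:
            raise DataError("planted motif destroyed during repair "
                            "(payload overlap?)")
        for _cls, start, stop, _unit in extra:
            pos = [i for i in range(start - 1, stop) if not protected[i]]
            if not pos:
                raise DataError("cannot repair: offending tract fully planted")
            i = pos[len(pos) // 2]
            cur = arr[i]
            choices = _BASES[_BASES != cur]
            arr[i] = choices[int(rng.integers(len(choices)))]
    raise DataError("background repair did not converge")


def _guard_base(neighbor_side: str, payload: str, left: bool,
                params: ScanParams, rng: np.random.Generator) -> int:
    """Pick a flank base that blocks Z-DNA and STR extension of a payload."""
    edge = payload[0] if left else payload[-1]
    # same purine/pyrimidine class as the adjacent payload base breaks
    # alternation
    candidates = list("AG" if edge in "AG" else "CT")
    banned = set()
    m = len(payload)
    for p in range(1, params.str_unit_max + 1):
        if m >= p:
            banned.add(payload[p - 1] if left else payload[m - p])
    ok = [c for c in candidates if c not in banned]
    pool = ok or candidates
    return ord(pool[int(rng.integers(len(pool)))])


def sim_genome(
    contig_lengths: Mapping[str, int],
    plants: Sequence[PlantSpec],
    seed: int,
    gc: float = 0.45,
    params: ScanParams | None = None,
    mode: str = "planted-only",
) -> tuple[dict[str, str], list[MotifHit]]:
    """Simulate genome sequences containing exactly the planted motifs.

    In ``planted-only`` mode the background is scrubbed (by targeted
    mutation of any scanner-valid tract) so the returned truth — the union
    of the plants' expected hits — equals the scanner output exactly.  In
    ``oracle`` mode the background is left as drawn and the truth is the
    scan of the emitted sequence.  Deterministic given ``seed``.
    """
    params = params or ScanParams()
    if mode not in ("planted-only", "oracle"):
        raise DataError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    by_contig: dict[str, list[PlantSpec]] = {c: [] for c in contig_lengths}
    for pl in plants:
        if pl.contig not in by_contig:
            raise DataError(f"plant on unknown contig {pl.contig!r}")
        by_contig[pl.contig].append(pl)

    records: dict[str, str] = {}
    truth: list[MotifHit] = []
    for contig, length in contig_lengths.items():
        if length <= 0:
            raise DataError(f"contig {contig!r}: non-positive length")
        if mode == "planted-only" and length > _PLANTED_ONLY_MAX_CONTIG:
            raise DataError(
                f"planted-only mode supports contigs <= "
                f"{_PLANTED_ONLY_MAX_CONTIG} bp; use mode='oracle'")
        contig_plants = sorted(by_contig[contig], key=lambda p: p.position)
        total_payload = sum(len(p.payload) + 2 for p in contig_plants)
        if total_payload > 0.6 * length:
            raise DataError(
                f"contig {contig!r}: requested plants ({total_payload} bp "
                f"with spacing) infeasible for length {length}")
        prev_end = 0
        for pl in contig_plants:
            if pl.position - 1 <= prev_end + 1:  # need >= 1 nt gap + guard
                raise DataError(
                    f"contig {contig!r}: plants too close at {pl.position}")
            if pl.end > length:
                raise DataError(
                    f"contig {contig!r}: plant at {pl.position} overruns "
                    "contig end")
            prev_end = pl.end

        arr = _random_background(rng, length, gc)
        protected = np.zeros(length, dtype=bool)
        contig_truth: list[MotifHit] = []
        for pl in contig_plants:
            i0 = pl.position - 1
            i1 = pl.end
            arr[i0:i1] = np.frombuffer(pl.payload.encode(), dtype=np.uint8)
            protected[i0:i1] = True
            if i0 > 0:
                arr[i0 - 1] = _guard_base("", pl.payload, True, params, rng)
            if i1 < length:
                arr[i1] = _guard_base("", pl.payload, False, params, rng)
            contig_truth.extend(pl.truth_hits(params))

        if mode == "planted-only":
            truth_keys = frozenset((h.motif_class, h.start, h.stop, h.unit)
                                   for h in contig_truth)
            arr = _repair(arr, contig, params, rng, truth_keys, protected)
            records[contig] = arr.tobytes().decode("ascii")
            truth.extend(sorted(contig_truth, key=lambda h: (h.start, h.stop)))
        else:
            seq = arr.tobytes().decode("ascii")
            records[contig] = seq
            truth.extend(_scan_all(seq, contig, params))
    return records, truth


def random_plants(
    contig_lengths: Mapping[str, int],
    n_zdna: int,
    n_str: int,
    seed: int,
    params: ScanParams | None = None,
    forbidden: Mapping[str, Sequence[tuple[int, int]]] | None = None,
) -> list[PlantSpec]:
    """Draw non-overlapping random plant positions and payloads.

    ``forbidden`` maps contig -> 1-based inclusive intervals that plants
    must avoid (e.g. gene start codons).
    """
    params = params or ScanParams()
    rng = np.random.default_rng(seed)
    contigs = list(contig_lengths)
    taken: dict[str, list[tuple[int, int]]] = {
        c: [tuple(iv) for iv in (forbidden or {}).get(c, [])] for c in contigs}
    out: list[PlantSpec] = []
    specs = [("ZDNA", None)] * n_zdna + [("STR", None)] * n_str
    for mclass, _ in specs:
        if mclass == "ZDNA":
            payload, unit, copies = random_zdna_payload(rng, None, params), "", 0
        else:
            payload, unit, copies = random_str_payload(rng, params)
        placed = False
        for _ in range(1000):
            contig = contigs[int(rng.integers(len(contigs)))]
            length = contig_lengths[contig]
            if length < len(payload) + 4:
                continue
            pos = int(rng.integers(3, length - len(payload) - 1))
            iv = (pos - 2, pos + len(payload) + 1)
            if any(iv[0] <= b and a <= iv[1] for a, b in taken[contig]):
                continue
            taken[contig].append(iv)
            out.append(PlantSpec(contig=contig, position=pos,
                                 motif_class=mclass, payload=payload,
                                 unit=unit, copies=copies))
            placed = True
            break
        if not placed:
            raise DataError("could not place all requested plants "
                            "(density infeasible for genome length)")
    return out


# ---------------------------------------------------------------------------
# Annotation simulation
# ---------------------------------------------------------------------------

def sim_annotation(
    contig_lengths: Mapping[str, int],
    n_genes: int,
    seed: int,
    strand_mix: float = 0.5,
    window_bp: int = 10_000,
    spacing_bp: int | None = None,
    allow_truncated: bool = False,
) -> tuple[list[GeneRecord], str]:
    """Place genes with start_codon features on both strands; returns
    (gene records, GTF text in Augustus-style dialect).

    Genes are spaced so their upstream windows are disjoint; each window
    fits inside its contig unless ``allow_truncated`` deliberately places
    genes near contig edges.
    """
    rng = np.random.default_rng(seed)
    spacing = spacing_bp if spacing_bp is not None else window_bp + 200
    slots: list[tuple[str, int, str]] = []
    for contig, length in contig_lengths.items():
        pos = window_bp + 3 if not allow_truncated else 3
        while pos + 3 <= length and len(slots) < n_genes * 2:
            strand = "+" if rng.random() < strand_mix else "-"
            if (strand == "-" and not allow_truncated
                    and pos + window_bp > length):
                strand = "+"  # downstream window would overrun the contig
            slots.append((contig, pos, strand))
            pos += spacing
    if len(slots) < n_genes:
        raise DataError(
            f"cannot place {n_genes} genes with window {window_bp} and "
            f"spacing {spacing} in the given contigs")
    slots = slots[:n_genes]
    genes = []
    gtf_lines = []
    for i, (contig, pos, strand) in enumerate(slots, start=1):
        gid = f"g{i}"
        genes.append(GeneRecord(gene_id=gid, seq_id=contig, strand=strand,
                                start_codon_pos=pos))
        if strand == "+":
            start, end = pos, pos + 2
        else:
            start, end = pos - 2, pos
        attrs = f'gene_id "{gid}"; transcript_id "{gid}.t1";'
        gtf_lines.append("\t".join([
            contig, "sim", "start_codon", str(start), str(end), ".",
            strand, "0", attrs]))
    return genes, "\n".join(gtf_lines) + "\n"


def sim_promoter_dataset(
    seed: int,
    contig_length: int = 450_000,
    n_genes: int = 20,
    bin_counts: Mapping[int, int] | None = None,
    window_bp: int = 10_000,
    bin_bp: int = 1_000,
    gc: float = 0.45,
    params: ScanParams | None = None,
) -> dict:
    """A genome + annotation in which each gene's upstream window carries a
    known number of Z-DNA motifs in chosen distance bins.

    ``bin_counts`` maps bin index (1-based) -> motifs planted per gene in
    that bin (default: one motif in bin 1 of every gene).  Gene windows are
    disjoint, so the expected region-matrix row follows directly from the
    plan.  Returns a dict with keys: records, genes, gtf, truth_hits,
    truth_bins (expected per-bin totals), params.
    """
    params = params or ScanParams()
    bin_counts = dict(bin_counts) if bin_counts else {1: 1}
    n_bins = window_bp // bin_bp
    if any(not (1 <= b <= n_bins) for b in bin_counts):
        raise DataError(f"bins must lie in 1..{n_bins}")
    rng = np.random.default_rng(seed)
    contigs = {"chrSim": contig_length}
    # gene windows must be pairwise disjoint so the planted bin plan maps
    # one-to-one onto assignments; a +/- gene pair needs 2 windows of space
    genes, gtf = sim_annotation(contigs, n_genes, seed=seed + 1,
                                window_bp=window_bp,
                                spacing_bp=2 * window_bp + 200)
    plants: list[PlantSpec] = []
    for g in genes:
        for b, count in bin_counts.items():
            lo_d = (b - 1) * bin_bp + 1
            hi_d = b * bin_bp
            for _ in range(count):
                payload = random_zdna_payload(rng, None, params)
                for _try in range(200):
                    distance = int(rng.integers(lo_d, hi_d + 1))
                    if g.strand == "+":
                        stop = g.start_codon_pos - distance
                        start = stop - len(payload) + 1
                    else:
                        start = g.start_codon_pos + distance
                        stop = start + len(payload) - 1
                    if start < 3 or stop > contig_length - 3:
                        continue
                    iv = (start - 2, stop + 2)
                    clash = any(
                        iv[0] <= p.end + 2 and p.position - 2 <= iv[1]
                        for p in plants)
                    codon = (g.start_codon_pos - 2, g.start_codon_pos + 2)
                    if clash or (iv[0] <= codon[1] and codon[0] <= iv[1]):
                        continue
                    plants.append(PlantSpec(
                        contig="chrSim", position=start, motif_class="ZDNA",
                        payload=payload))
                    break
                else:
                    raise DataError("could not place promoter plant")
    records, truth = sim_genome(contigs, plants, seed=seed + 2, gc=gc,
                                params=params)
    truth_bins = np.zeros(n_bins, dtype=int)
    for b, count in bin_counts.items():
        truth_bins[b - 1] = count * n_genes
    return {"records": records, "genes": genes, "gtf": gtf,
            "truth_hits": truth, "truth_bins": truth_bins, "params": params,
            "window_bp": window_bp, "bin_bp": bin_bp}


# ---------------------------------------------------------------------------
# Trees and traits
# ---------------------------------------------------------------------------

def sim_yule_tree(n_tips: int, birth_rate: float = 1.0, seed: int = 0) -> str:
    """Ultrametric pure-birth tree as a newick string.

    Waiting time from k to k+1 lineages is Exp(birth_rate * k); after the
    n-th lineage appears the process runs one further Exp(birth_rate * n)
    before the present, so E[height] = sum_{k=2..n} 1/(birth_rate * k).
    """
    if n_tips < 3:
        raise DataError("n_tips must be >= 3")
    if birth_rate <= 0:
        raise DataError("birth_rate must be > 0")
    rng = np.random.default_rng(seed)
    # node: [children, birth_time, edge_length]
    root = {"children": [], "birth": 0.0, "len": 0.0}
    a = {"children": [], "birth": 0.0, "len": None}
    b = {"children": [], "birth": 0.0, "len": None}
    root["children"] = [a, b]
    active = [a, b]
    t = 0.0
    k = 2
    while k < n_tips:
        t += rng.exponential(1.0 / (birth_rate * k))
        i = int(rng.integers(k))
        node = active[i]
        node["len"] = t - node["birth"]
        c1 = {"children": [], "birth": t, "len": None}
        c2 = {"children": [], "birth": t, "len": None}
        node["children"] = [c1, c2]
        active[i] = c1
        active.append(c2)
        k += 1
    t += rng.exponential(1.0 / (birth_rate * n_tips))
    for node in active:
        node["len"] = t - node["birth"]

    counter = {"i": 0}

    def emit(node) -> str:
        if not node["children"]:
            counter["i"] += 1
            return f"T{counter['i']}:{node['len']:.10f}"
        inner = ",".join(emit(c) for c in node["children"])
        return f"({inner}):{node['len']:.10f}"

    return emit(root) + ";"


def sim_trait(tree: Phylogeny, model: str, seed: int,
              sigma2: float = 1.0, shape_param: float | None = None,
              mu: float = 0.0) -> pd.Series:
    """Draw one trait vector from MVN(mu 1, sigma^2 V(model, shape))."""
    if sigma2 < 0:
        raise DataError("sigma2 must be >= 0")
    rng = np.random.default_rng(seed)
    if sigma2 == 0:
        vals = np.full(tree.n, mu)
    else:
        V = model_covariance(tree, model, shape_param)
        L = np.linalg.cholesky(sigma2 * V + 1e-12 * np.eye(tree.n))
        vals = mu + L @ rng.standard_normal(tree.n)
    return pd.Series(vals, index=tree.tip_labels, name="trait")


def sim_regression_dataset(tree: Phylogeny, x: pd.Series | Sequence[float],
                           beta: tuple[float, float], model: str, seed: int,
                           sigma2: float = 1.0,
                           shape_param: float | None = None
                           ) -> tuple[pd.Series, pd.Series]:
    """y = beta0 + beta1 x + MVN(0, sigma^2 V) residuals on the tree."""
    if sigma2 <= 0:
        raise DataError("sigma2 must be > 0")
    xv = x.reindex(tree.tip_labels).to_numpy() if isinstance(x, pd.Series) \
        else np.asarray(x, dtype=float)
    if xv.shape != (tree.n,) or not np.isfinite(xv).all():
        raise DataError("x must provide one finite value per tip")
    rng = np.random.default_rng(seed)
    V = model_covariance(tree, model, shape_param)
    L = np.linalg.cholesky(sigma2 * V + 1e-12 * np.eye(tree.n))
    y = beta[0] + beta[1] * xv + L @ rng.standard_normal(tree.n)
    return (pd.Series(xv, index=tree.tip_labels, name="x"),
            pd.Series(y, index=tree.tip_labels, name="y"))
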