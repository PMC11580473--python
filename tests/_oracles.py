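"""Independent brute-force oracles used to validate the implementation.

Everything here works straight from definitions (substring enumeration,
explicit maximality checks, dense joint covariances, exhaustive permutation
nulls, numerical quadrature) and shares no code with the package internals.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import integrate
from scipy import stats as sstats

ACGT = set("ACGT")


def _zdna_pair_ok(a: str, b: str, allow_at: bool) -> bool:
    if a not in ACGT or b not in ACGT:
        return False
    if (a in "AG") == (b in "AG"):
        return False
    if not allow_at and {a, b} == {"A", "T"}:
        return False
    return True


def _zdna_valid(sub: str, allow_at: bool) -> bool:
    if any(c not in ACGT for c in sub):
        return False
    return all(_zdna_pair_ok(x, y, allow_at) for x, y in zip(sub, sub[1:]))


def zdna_oracle(seq: str, min_len: int = 10, allow_at: bool = False,
                softmask_ok: bool = True) -> list[tuple[int, int]]:
    """All maximal valid Z-DNA tracts as 1-based (start, stop) pairs, by
    testing every candidate substring for validity and maximality."""
    s = seq.upper() if softmask_ok else "".join(
        c if c in ACGT else "N" for c in seq)
    n = len(s)
    out = []
    for i in range(n):
        j_best = None
        for j in range(i + min_len, n + 1):
            if _zdna_valid(s[i:j], allow_at):
                j_best = j
            else:
                break
        if j_best is None:
            continue
        left_ext = i > 0 and _zdna_valid(s[i - 1:j_best], allow_at)
        right_ext = j_best < n and _zdna_valid(s[i:j_best + 1], allow_at)
        if not left_ext and not right_ext:
            out.append((i + 1, j_best))
    return out


def _primitive(unit: str) -> bool:
    p = len(unit)
    return all(unit != unit[:d] * (p // d)
               for d in range(1, p) if p % d == 0)


def str_oracle(seq: str, unit_min: int = 2, unit_max: int = 6,
               min_copies: int = 3, min_len: int = 10,
               softmask_ok: bool = True
               ) -> list[tuple[int, int, str, int]]:
    """All maximal perfect tandem tracts as (start, stop, unit, copies),
    1-based inclusive, brute force over unit sizes and phases."""
    s = seq.upper() if softmask_ok else "".join(
        c if c in ACGT else "N" for c in seq)
    n = len(s)
    out = set()
    for p in range(unit_min, unit_max + 1):
        for i in range(n - p):
            unit = s[i:i + p]
            if any(c not in ACGT for c in unit) or not _primitive(unit):
                continue
            j = i + p
            while j < n and s[j] in ACGT and s[j] == s[j - p]:
                j += 1
            length = j - i
            if length <= p:
                continue
            copies = length // p
            if length < min_len or copies < min_copies:
                continue
            # left-maximality: the tract must not extend by one base leftwards
            if i > 0 and s[i - 1] in ACGT and s[i - 1] == s[i - 1 + p]:
                continue
            out.add((i + 1, j, unit, copies))
    return sorted(out)


def revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTacgt", "TGCAtgca"))[::-1]


# ---------------------------------------------------------------------------
# Rank statistics
# ---------------------------------------------------------------------------

def _friedman_stat_reference(m: np.ndarray) -> float:
    """Tie-corrected Friedman chi-square computed straight from ranks."""
    n, k = m.shape
    R = np.vstack([sstats.rankdata(row) for row in m])
    S = np.sum((R.sum(axis=0) - n * (k + 1) / 2.0) ** 2)
    ties = sum(float(np.sum(c ** 3 - c))
               for c in (np.unique(row, return_counts=True)[1] for row in m))
    denom = n * k * (k + 1) / 12.0 - ties / (12.0 * (k - 1))
    if denom <= 0:
        return 0.0
    return S / denom


def friedman_permutation_pvalue(matrix: np.ndarray) -> float:
    """Exact permutation p-value of the Friedman statistic for a small
    complete matrix: enumerate every within-block ordering."""
    m = np.asarray(matrix, dtype=float)
    n, k = m.shape
    obs = _friedman_stat_reference(m)
    perms = list(itertools.permutations(range(k)))
    count = 0
    total = 0
    for combo in itertools.product(perms, repeat=n):
        perm_m = np.vstack([m[b, list(combo[b])] for b in range(n)])
        total += 1
        if _friedman_stat_reference(perm_m) >= obs - 1e-12:
            count += 1
    return count / total


def studentized_range_tail_quadrature(q: float, k: int) -> float:
    """P(Q_{k,inf} >= q) by direct numerical integration of the classical
    density-free representation:
    P(Q < q) = k * int phi(z) [Phi(z) - Phi(z - q)]^(k-1) dz."""
    if q <= 0:
        return 1.0

    def integrand(z: float) -> float:
        return sstats.norm.pdf(z) * (
            sstats.norm.cdf(z) - sstats.norm.cdf(z - q)) ** (k - 1)

    cdf, _ = integrate.quad(integrand, -np.inf, np.inf, limit=200)
    return 1.0 - k * cdf


# ---------------------------------------------------------------------------
# Phylogenetics
# ---------------------------------------------------------------------------

def bm_covariance_dendropy(phy) -> np.ndarray:
    """Shared path length (root-to-MRCA) for every tip pair, computed with
    dendropy's own MRCA machinery rather than the package's traversal."""
    tree = phy.dendropy_tree
    taxa = {t.label: t for t in tree.taxon_namespace}
    labels = phy.tip_labels
    n = len(labels)

    def root_dist(node) -> float:
        d = 0.0
        while node.parent_node is not None:
            d += node.edge.length or 0.0
            node = node.parent_node
        return d

    C = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            mrca = tree.mrca(taxa=[taxa[labels[i]], taxa[labels[j]]])
            C[i, j] = C[j, i] = root_dist(mrca)
    return C


def ancestral_states_joint_gls(phy, x: np.ndarray) -> np.ndarray:
    """BM ancestral states via the dense joint tips+nodes covariance:
    conditional expectation a = mu + S_at S_tt^{-1} (x - mu 1) with mu the
    GLS root-state estimate.  Ordered as phy.internal_ids."""
    tree = phy.dendropy_tree
    tips = list(tree.leaf_node_iter())
    internal = [nd for nd in tree.preorder_node_iter() if not nd.is_leaf()]

    def root_dist(node) -> float:
        d = 0.0
        while node.parent_node is not None:
            d += node.edge.length or 0.0
            node = node.parent_node
        return d

    def mrca_depth(a, b):
        anc_a = set()
        n = a
        while n is not None:
            anc_a.add(n)
            n = n.parent_node
        n = b
        while n not in anc_a:
            n = n.parent_node
        return root_dist(n)

    Stt = np.array([[mrca_depth(a, b) for b in tips] for a in tips])
    Sat = np.array([[mrca_depth(a, b) for b in tips] for a in internal])
    ones = np.ones(len(tips))
    Stt_inv = np.linalg.inv(Stt)
    mu = float(ones @ Stt_inv @ x / (ones @ Stt_inv @ ones))
    return mu + Sat @ Stt_inv @ (x - mu)
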