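"""Pairwise TN93 distances, neighbour joining, and bootstrap support.

The Tamura–Nei (1993) distance separates purine transitions, pyrimidine
transitions and transversions, with base frequencies estimated from the two
sequences of each pair pooled (``global_freqs=True`` switches to
alignment-wide frequencies).  Neighbour joining uses the standard
Q-criterion with deterministic lowest-index tie-breaking; negative branch
lengths are clamped to zero and the clamped deficit logged.  Bootstrap
support resamples alignment columns with replacement and maps bipartition
frequencies onto the full-data tree.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import dendropy
import numpy as np

log = logging.getLogger(__name__)

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
SATURATED = math.inf  # marker distance when a log argument is non-positive


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric matrix of pairwise distances with zero diagonal."""

    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValueError("matrix shape does not match taxon count")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("diagonal must be zero")
        finite = np.isfinite(v)
        if not np.allclose(v[finite & finite.T], v.T[finite & finite.T]):
            raise ValueError("matrix must be symmetric")
        if np.any(v[finite] < 0):
            raise ValueError("distances must be non-negative")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def has_saturated(self) -> bool:
        return bool(np.any(~np.isfinite(self.values)))


def encode_alignment(sequences: dict[str, str]) -> tuple[tuple[str, ...], np.ndarray]:
    """Alignment dict → (ids, n×L uint8 matrix); non-ACGT codes become 4."""
    ids = tuple(sequences)
    lengths = {len(s) for s in sequences.values()}
    if len(lengths) != 1:
        raise ValueError("alignment sequences must share one length")
    L = lengths.pop()
    M = np.full((len(ids), L), 4, dtype=np.uint8)
    for i, sid in enumerate(ids):
        row = np.frombuffer(sequences[sid].upper().encode("ascii"), dtype=np.uint8)
        for base, code in _CODE.items():
            M[i, row == ord(base)] = code
    return ids, M


def _pair_stats(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float, np.ndarray, int]:
    valid = (a < 4) & (b < 4)
    aa, bb = a[valid], b[valid]
    L = aa.size
    if L == 0:
        raise ValueError("no comparable sites between the two sequences")
    diff = aa != bb
    same_parity = (aa % 2) == (bb % 2)
    p1 = int(np.count_nonzero(diff & same_parity & (aa % 2 == 0)))  # A<->G
    p2 = int(np.count_nonzero(diff & same_parity & (aa % 2 == 1)))  # C<->T
    q = int(np.count_nonzero(diff & ~same_parity))
    pooled = np.bincount(np.concatenate([aa, bb]), minlength=4) / (2 * L)
    return p1 / L, p2 / L, q / L, pooled, L


def tn93_from_proportions(
    P1: float, P2: float, Q: float, freqs: Sequence[float]
) -> float:
    """TN93 distance from observed proportions and base frequencies.

    Returns :data:`SATURATED` (+inf) when any logarithm argument is
    non-positive.
    """
    gA, gC, gG, gT = freqs
    gR, gY = gA + gG, gC + gT
    d = 0.0
    k1 = 2 * gA * gG / gR if gR > 0 else 0.0
    if k1 > 0:
        arg = 1 - P1 / k1 - Q / (2 * gR)
        if arg <= 0:
            return SATURATED
        d -= k1 * math.log(arg)
    elif P1 > 0:
        return SATURATED
    k2 = 2 * gC * gT / gY if gY > 0 else 0.0
    if k2 > 0:
        arg = 1 - P2 / k2 - Q / (2 * gY)
        if arg <= 0:
            return SATURATED
        d -= k2 * math.log(arg)
    elif P2 > 0:
        return SATURATED
    k3 = 2 * (
        gR * gY
        - (gA * gG * gY / gR if gR > 0 else 0.0)
        - (gC * gT * gR / gY if gY > 0 else 0.0)
    )
    if gR * gY > 0:
        arg = 1 - Q / (2 * gR * gY)
        if arg <= 0:
            return SATURATED
        d -= k3 * math.log(arg)
    elif Q > 0:
        return SATURATED
    return max(d, 0.0)


def tn93_distance(seq_a, seq_b, freqs: Sequence[float] | None = None) -> float:
    """TN93 distance between two aligned sequences (strings or coded arrays).

    Sites with a non-ACGT code in either sequence are ignored pairwise.
    ``freqs`` overrides the pooled two-sequence base frequencies.
    """
    if isinstance(seq_a, str):
        _, M = encode_alignment({"a": seq_a, "b": seq_b})
        a, b = M[0], M[1]
    else:
        a, b = np.asarray(seq_a), np.asarray(seq_b)
    P1, P2, Q, pooled, _ = _pair_stats(a, b)
    return tn93_from_proportions(P1, P2, Q, pooled if freqs is None else freqs)


def p_distance(seq_a, seq_b) -> float:
    """Raw proportion of differing sites (ignoring non-ACGT pairwise)."""
    if isinstance(seq_a, str):
        _, M = encode_alignment({"a": seq_a, "b": seq_b})
        a, b = M[0], M[1]
    else:
        a, b = np.asarray(seq_a), np.asarray(seq_b)
    P1, P2, Q, _, _ = _pair_stats(a, b)
    return P1 + P2 + Q


def distance_matrix(
    sequences: dict[str, str] | tuple[tuple[str, ...], np.ndarray],
    model: str = "tn93",
    global_freqs: bool = False,
) -> DistanceMatrix:
    """All-pairs distance matrix under ``tn93`` or raw ``p`` distance."""
    if isinstance(sequences, dict):
        ids, M = encode_alignment(sequences)
    else:
        ids, M = sequences
    n = len(ids)
    freqs = None
    if global_freqs:
        counts = np.bincount(M[M < 4].ravel(), minlength=4)
        freqs = counts / counts.sum()
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if model == "tn93":
                dij = tn93_distance(M[i], M[j], freqs=freqs)
            elif model == "p":
                dij = p_distance(M[i], M[j])
            else:
                raise ValueError(f"unknown model {model!r}")
            d[i, j] = d[j, i] = dij
    return DistanceMatrix(ids, d)


# ---------------------------------------------------------------------------
# neighbour joining
# ---------------------------------------------------------------------------


def nj_tree(dm: DistanceMatrix, taxon_namespace: dendropy.TaxonNamespace | None = None) -> dendropy.Tree:
    """Neighbour-joining tree by Q-criterion agglomeration.

    Ties in the Q minimum break on the lowest (i, j) index pair, making
    runs deterministic.  Negative branch lengths are clamped to zero.
    Raises on fewer than 3 taxa or non-finite (saturated) distances.
    """
    if dm.n < 3:
        raise ValueError("neighbour joining requires at least 3 taxa")
    if dm.has_saturated:
        raise ValueError(
            "distance matrix contains saturated (infinite) entries; "
            "recompute distances or drop the affected taxa"
        )
    ns = taxon_namespace or dendropy.TaxonNamespace(list(dm.ids))
    nodes: dict[int, dendropy.Node] = {}
    for i, tid in enumerate(dm.ids):
        taxon = ns.get_taxon(tid)
        if taxon is None:
            taxon = ns.new_taxon(tid)
        nodes[i] = dendropy.Node(taxon=taxon)

    size = 2 * dm.n  # work matrix generously sized for joined nodes
    d = np.zeros((size, size))
    d[: dm.n, : dm.n] = dm.values
    active = list(range(dm.n))
    next_idx = dm.n
    clamped = 0.0

    def _clamp(x: float) -> float:
        nonlocal clamped
        if x < 0:
            clamped += -x
            return 0.0
        return x

    while len(active) > 3:
        r = len(active)
        sub = d[np.ix_(active, active)]
        R = sub.sum(axis=1)
        Q = (r - 2) * sub - R[:, None] - R[None, :]
        # evaluate on the upper triangle only (subtraction order makes Q
        # asymmetric at the last ulp); argmin's first hit is the lowest
        # (i, j) pair in row-major order, giving deterministic tie-breaks
        iu = np.triu_indices(r, k=1)
        k = int(np.argmin(Q[iu]))
        i, j = int(iu[0][k]), int(iu[1][k])
        ai, aj = active[i], active[j]
        dij = sub[i, j]
        vi = _clamp(0.5 * dij + (R[i] - R[j]) / (2 * (r - 2)))
        vj = _clamp(dij - (0.5 * dij + (R[i] - R[j]) / (2 * (r - 2))))
        parent = dendropy.Node()
        parent.add_child(nodes[ai])
        nodes[ai].edge.length = vi
        parent.add_child(nodes[aj])
        nodes[aj].edge.length = vj
        for k in active:
            if k in (ai, aj):
                continue
            d[next_idx, k] = d[k, next_idx] = 0.5 * (d[ai, k] + d[aj, k] - dij)
        nodes[next_idx] = parent
        active = [k for k in active if k not in (ai, aj)] + [next_idx]
        next_idx += 1

    a, b, c = active
    center = dendropy.Node()
    la = _clamp(0.5 * (d[a, b] + d[a, c] - d[b, c]))
    lb = _clamp(0.5 * (d[a, b] + d[b, c] - d[a, c]))
    lc = _clamp(0.5 * (d[a, c] + d[b, c] - d[a, b]))
    for idx, length in ((a, la), (b, lb), (c, lc)):
        center.add_child(nodes[idx])
        nodes[idx].edge.length = length

    tree = dendropy.Tree(taxon_namespace=ns)
    tree.seed_node = center
    tree.is_rooted = False
    if clamped > 0:
        log.info("clamped negative branch lengths; total deficit %.6g", clamped)
    return tree


def tree_length(tree: dendropy.Tree) -> float:
    return sum(e.length or 0.0 for e in tree.preorder_edge_iter() if e.length is not None)


def _internal_split_masks(tree: dendropy.Tree) -> set[int]:
    tree.encode_bipartitions()
    masks = set()
    for edge in tree.preorder_edge_iter():
        head = edge.head_node
        if head is tree.seed_node or head.is_leaf():
            continue
        masks.add(edge.bipartition.split_bitmask)
    return masks


def bootstrap_support(
    sequences: dict[str, str],
    reps: int = 500,
    seed: int | None = None,
    model: str = "tn93",
    global_freqs: bool = False,
) -> dendropy.Tree:
    """Full-data NJ tree with bootstrap support percentages on internal nodes.

    Alignment columns are resampled with replacement ``reps`` times; each
    internal edge of the full-data tree is labelled with the percentage of
    replicate trees containing the same bipartition.  The seed fully
    determines the output.  A degenerate alignment (no variable sites)
    yields a star-consensus with all supports defined as 100 and a warning.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if seed is None:
        raise ValueError("a seed is required for reproducible bootstrapping")
    ids, M = encode_alignment(sequences)
    ns = dendropy.TaxonNamespace(list(ids))
    full_dm = distance_matrix((ids, M), model=model, global_freqs=global_freqs)
    tree = nj_tree(full_dm, taxon_namespace=ns)

    variable = np.any(M != M[0], axis=0)
    degenerate = not bool(variable.any())
    if degenerate:
        warnings.warn("alignment has no variable sites; supports defined as 100")

    counts: dict[int, int] = {}
    tree.encode_bipartitions()
    target_edges = []
    for edge in tree.preorder_edge_iter():
        head = edge.head_node
        if head is tree.seed_node or head.is_leaf():
            continue
        target_edges.append(edge)
        counts[edge.bipartition.split_bitmask] = 0

    rng = np.random.default_rng(seed)
    L = M.shape[1]
    for _ in range(reps):
        cols = rng.integers(0, L, size=L)
        rep_dm = distance_matrix((ids, M[:, cols]), model=model, global_freqs=global_freqs)
        try:
            rep_tree = nj_tree(rep_dm, taxon_namespace=ns)
        except ValueError:
            continue  # saturated replicate contributes no support
        for mask in _internal_split_masks(rep_tree):
            if mask in counts:
                counts[mask] += 1

    for edge in target_edges:
        pct = 100.0 if degenerate else 100.0 * counts[edge.bipartition.split_bitmask] / reps
        edge.head_node.label = str(int(round(pct)))
    return tree


def write_newick(tree: dendropy.Tree, path) -> None:
    with open(path, "w") as fh:
        fh.write(
            tree.as_string(
                schema="newick",
                suppress_rooting=True,
                unquoted_underscores=True,
            )
        )
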