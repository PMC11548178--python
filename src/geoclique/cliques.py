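"""Maximal-clique enumeration and hypothesis selection.

Each vertex of the binarized compatibility graph is one correspondence; a
maximal clique is a mutually compatible correspondence set that cannot be
extended — a registration hypothesis. Enumeration is Bron–Kerbosch with
pivoting, run over a degeneracy ordering at the outer level (the Eppstein
variant), which is near-optimal on the sparse graphs that thresholded
compatibility produces. Adjacency is the *unweighted* binary graph; the
second-order weights only enter at selection time.

Selection follows a node-guided vetting rule: for every graph node, only the
highest-total-weight maximal clique containing it survives (total weight =
sum of SC2 over the clique's internal pairs), survivors are deduplicated and
ranked by weight.

Vertex sets are manipulated as Python integer bitmasks, which keeps the
recursion fast without compiled code for the graph sizes this pipeline sees
(hundreds of correspondences).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .mesh import InputError

__all__ = ["CliqueHypothesis", "enumerate_maximal_cliques", "select_hypotheses"]

DEFAULT_MIN_SIZE = 3  # a 2-clique cannot constrain an articulation
DEFAULT_MAX_CLIQUES = 10_000


@dataclasses.dataclass
class CliqueHypothesis:
    member_ids: tuple  # sorted correspondence indices
    total_weight: float  # sum of SC2 edge weights over internal pairs
    rank: int

    def to_json_dict(self) -> dict:
        return {
            "member_ids": list(self.member_ids),
            "total_weight": self.total_weight,
            "rank": self.rank,
        }


def _check_adjacency(C_bin: np.ndarray) -> np.ndarray:
    C = np.asarray(C_bin)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise InputError("adjacency must be square")
    if not np.isin(C, (0, 1)).all():
        raise InputError("adjacency must be binary")
    if not np.array_equal(C, C.T):
        raise InputError("adjacency must be symmetric")
    if np.any(np.diag(C) != 0):
        raise InputError("adjacency must have zero diagonal")
    return C.astype(bool)


def _degeneracy_order(adj_masks: list, n: int) -> list:
    """Vertex order of repeatedly removing a minimum-degree vertex.

    Ties are broken toward the lowest index, so the ordering — and hence the
    enumeration — is deterministic and permutation-equivariant.
    """
    remaining = (1 << n) - 1
    degree = [bin(adj_masks[v]).count("1") for v in range(n)]
    order = []
    alive = [True] * n
    for _ in range(n):
        best, best_deg = -1, n + 1
        for v in range(n):
            if alive[v] and degree[v] < best_deg:
                best, best_deg = v, degree[v]
        order.append(best)
        alive[best] = False
        remaining &= ~(1 << best)
        m = adj_masks[best] & remaining
        while m:
            low = m & -m
            degree[low.bit_length() - 1] -= 1
            m ^= low
    return order


class _Truncated(Exception):
    pass


def _bk_pivot(R: int, P: int, X: int, adj: list, out: list, cap: int) -> None:
    if P == 0 and X == 0:
        out.append(R)
        if len(out) >= cap:
            raise _Truncated
        return
    # pivot: vertex of P | X with the most neighbors in P (ties -> lowest index)
    best_u, best_cnt = -1, -1
    m = P | X
    while m:
        low = m & -m
        u = low.bit_length() - 1
        cnt = bin(adj[u] & P).count("1")
        if cnt > best_cnt:
            best_u, best_cnt = u, cnt
        m ^= low
    cand = P & ~adj[best_u]
    while cand:
        low = cand & -cand
        v = low.bit_length() - 1
        _bk_pivot(R | low, P & adj[v], X & adj[v], adj, out, cap)
        P &= ~low
        X |= low
        cand ^= low
    return


def enumerate_maximal_cliques(
    C_bin: np.ndarray,
    min_size: int = DEFAULT_MIN_SIZE,
    max_cliques: int = DEFAULT_MAX_CLIQUES,
) -> tuple[list, bool]:
    """All maximal cliques of size >= ``min_size``.

    Returns ``(cliques, truncated)`` where each clique is a sorted tuple of
    vertex indices. Enumeration is exhaustive unless ``max_cliques`` maximal
    cliques (of any size) have been emitted, in which case ``truncated`` is
    True and the result is a prefix of the deterministic enumeration order.
    """
    C = _check_adjacency(C_bin)
    n = C.shape[0]
    if n == 0:
        return [], False
    adj = []
    for v in range(n):
        mask = 0
        for u in np.nonzero(C[v])[0]:
            mask |= 1 << int(u)
        adj.append(mask)
    order = _degeneracy_order(adj, n)
    out: list = []
    truncated = False
    P_mask = (1 << n) - 1
    done = 0
    try:
        for v in order:
            bit = 1 << v
            later = P_mask & ~done & ~bit
            _bk_pivot(bit, adj[v] & later, adj[v] & done, adj, out, max_cliques)
            done |= bit
    except _Truncated:
        truncated = True
    cliques = []
    for mask in out:
        members = []
        while mask:
            low = mask & -mask
            members.append(low.bit_length() - 1)
            mask ^= low
        if len(members) >= min_size:
            cliques.append(tuple(members))
    cliques.sort()
    return cliques, truncated


def verify_maximal_clique(C_bin: np.ndarray, members) -> bool:
    """Independent O(n * |clique|) check of clique-ness and maximality."""
    C = np.asarray(C_bin, dtype=bool)
    members = sorted(members)
    for a_pos, a in enumerate(members):
        for b in members[a_pos + 1 :]:
            if not C[a, b]:
                return False
    outside = np.setdiff1d(np.arange(C.shape[0]), members)
    for v in outside:
        if all(C[v, m] for m in members):
            return False
    return True


def select_hypotheses(
    cliques: list,
    SC2: np.ndarray,
    top_k: int | None = None,
) -> list:
    """Node-guided clique vetting.

    For each node, keep only its highest-total-weight containing clique;
    deduplicate the survivors, sort descending by weight (ties toward the
    lexicographically smallest member tuple) and truncate to ``top_k``.
    """
    SC2 = np.asarray(SC2, dtype=np.float64)
    n = SC2.shape[0]
    weights = []
    for cl in cliques:
        idx = np.asarray(cl)
        if idx.min(initial=0) < 0 or idx.max(initial=-1) >= n:
            raise InputError(f"clique {cl} references a node absent from SC2")
        sub = SC2[np.ix_(idx, idx)]
        weights.append(float(np.triu(sub, k=1).sum()))
    best_for_node: dict = {}
    for ci, (cl, w) in enumerate(zip(cliques, weights)):
        for v in cl:
            cur = best_for_node.get(v)
            # ties toward the lexicographically smaller clique: deterministic
            if cur is None or w > weights[cur] or (
                w == weights[cur] and cliques[ci] < cliques[cur]
            ):
                best_for_node[v] = ci
    surviving = sorted(set(best_for_node.values()))
    ranked = sorted(surviving, key=lambda ci: (-weights[ci], cliques[ci]))
    if top_k is not None:
        ranked = ranked[:top_k]
    return [
        CliqueHypothesis(member_ids=tuple(cliques[ci]), total_weight=weights[ci], rank=r)
        for r, ci in enumerate(ranked)
    ]


def save_hypotheses_jsonl(hypotheses: list, path) -> None:
    import json

    with open(path, "w") as fh:
        for h in hypotheses:
            fh.write(json.dumps(h.to_json_dict()) + "\n")
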