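"""Pedigree container and numerator relationship matrix (NRM) algebra.

The additive (numerator) relationship matrix A holds expected additive
genetic relationships between animals given the pedigree.  This module
provides the tabular method for A, Meuwissen & Luo style inbreeding
coefficients, Henderson's rules for the sparse direct inverse of A (with
inbreeding), and the genotyped-animal block A22 used by single-step
evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

UNKNOWN = -1


class PedigreeError(ValueError):
    """Invalid pedigree (cycle, duplicate id, missing animal)."""


class Pedigree:
    """Ordered pedigree with parents stored before their offspring.

    Parameters
    ----------
    ids : sequence of str
        Animal identifiers, already in a valid (parents-first) order.
    sire, dam : int arrays
        Index of each animal's sire/dam in ``ids``; ``UNKNOWN`` (-1) for an
        unknown parent.  Unknown parents are treated as unrelated,
        non-inbred founders (no genetic groups).
    """

    def __init__(self, ids: Sequence[str], sire: np.ndarray, dam: np.ndarray):
        self.ids = list(map(str, ids))
        self.sire = np.asarray(sire, dtype=np.int64)
        self.dam = np.asarray(dam, dtype=np.int64)
        if not (len(self.ids) == self.sire.size == self.dam.size):
            raise PedigreeError("ids/sire/dam length mismatch")
        n = len(self.ids)
        if len(set(self.ids)) != n:
            raise PedigreeError("duplicate animal ids")
        for name, par in (("sire", self.sire), ("dam", self.dam)):
            bad = np.nonzero(par >= np.arange(n))[0]
            if bad.size:
                raise PedigreeError(
                    f"pedigree not sorted parents-before-offspring: {name} of "
                    f"animal {self.ids[bad[0]]!r} does not precede it"
                )
        self._index = {a: i for i, a in enumerate(self.ids)}

    # ------------------------------------------------------------------
    @classmethod
    def from_triples(
        cls, triples: Iterable[tuple[str, str, str]], unknown: tuple[str, ...] = ("0", "", "NA")
    ) -> "Pedigree":
        """Build a pedigree from (animal, sire, dam) string triples.

        Rows may appear in any order; a topological sort places parents
        before offspring.  Parents that never appear in the animal column
        are added as founders.  Raises :class:`PedigreeError` on duplicate
        animal ids or on a cycle (e.g. an animal that is its own ancestor),
        naming one offending id.
        """
        rows = [(str(a), str(s), str(d)) for a, s, d in triples]
        seen: dict[str, tuple[str | None, str | None]] = {}
        order: list[str] = []
        for a, s, d in rows:
            if a in seen:
                raise PedigreeError(f"duplicate animal id {a!r}")
            s = None if s in unknown else s
            d = None if d in unknown else d
            seen[a] = (s, d)
            order.append(a)
        # implicit founders for parents never listed as animals
        for a in list(seen):
            for p in seen[a]:
                if p is not None and p not in seen:
                    seen[p] = (None, None)
                    order.append(p)

        # stable Kahn topological sort over parent -> offspring edges
        # (an input already in parents-first order round-trips unchanged)
        import heapq

        rank = {a: i for i, a in enumerate(order)}
        n_parents = {a: sum(p is not None for p in ps) for a, ps in seen.items()}
        children: dict[str, list[str]] = {a: [] for a in seen}
        for a, ps in seen.items():
            for p in ps:
                if p is not None:
                    children[p].append(a)
        ready = [rank[a] for a in order if n_parents[a] == 0]
        heapq.heapify(ready)
        sorted_ids: list[str] = []
        while ready:
            a = order[heapq.heappop(ready)]
            sorted_ids.append(a)
            for c in children[a]:
                n_parents[c] -= 1
                if n_parents[c] == 0:
                    heapq.heappush(ready, rank[c])
        if len(sorted_ids) != len(seen):
            offender = next(a for a in order if n_parents[a] > 0)
            raise PedigreeError(f"pedigree cycle detected involving animal {offender!r}")

        idx = {a: i for i, a in enumerate(sorted_ids)}
        sire = np.full(len(sorted_ids), UNKNOWN, dtype=np.int64)
        dam = np.full(len(sorted_ids), UNKNOWN, dtype=np.int64)
        for a, (s, d) in seen.items():
            i = idx[a]
            if s is not None:
                sire[i] = idx[s]
            if d is not None:
                dam[i] = idx[d]
        return cls(sorted_ids, sire, dam)

    # ------------------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def founders(self) -> np.ndarray:
        """Boolean mask of animals with both parents unknown."""
        return (self.sire == UNKNOWN) & (self.dam == UNKNOWN)

    def indices(self, ids: Iterable[str]) -> np.ndarray:
        """Positions of the given animal ids (error on unknown id)."""
        try:
            return np.array([self._index[str(a)] for a in ids], dtype=np.int64)
        except KeyError as e:  # pragma: no cover - message matters, not path
            raise PedigreeError(f"animal id {e.args[0]!r} not in pedigree") from None

    def __contains__(self, animal: str) -> bool:
        return str(animal) in self._index

    def __repr__(self) -> str:
        return f"Pedigree(n={self.n}, founders={int(self.founders.sum())})"


@dataclass
class Nrm:
    """Numerator relationship matrix with its inbreeding vector."""

    matrix: np.ndarray
    inbreeding: np.ndarray
    ids: list[str] = field(default_factory=list)


def nrm(pedigree: Pedigree) -> Nrm:
    """Numerator relationship matrix by the tabular method.

    a(i,i) = 1 + 0.5 a(s_i, d_i); a(i,j) = 0.5 (a(j,s_i) + a(j,d_i)) for j<i,
    with unknown parents contributing zero relationship.
    """
    n = pedigree.n
    A = np.zeros((n, n))
    s, d = pedigree.sire, pedigree.dam
    for i in range(n):
        si, di = s[i], d[i]
        if si >= 0 and di >= 0:
            A[i, :i] = 0.5 * (A[si, :i] + A[di, :i])
            A[i, i] = 1.0 + 0.5 * A[si, di]
        elif si >= 0:
            A[i, :i] = 0.5 * A[si, :i]
            A[i, i] = 1.0
        elif di >= 0:
            A[i, :i] = 0.5 * A[di, :i]
            A[i, i] = 1.0
        else:
            A[i, i] = 1.0
        A[:i, i] = A[i, :i]
    return Nrm(matrix=A, inbreeding=np.diag(A) - 1.0, ids=list(pedigree.ids))


def inbreeding(pedigree: Pedigree) -> np.ndarray:
    """Inbreeding coefficients F without forming the full A.

    Recursive kinship with memoisation (the recursion Meuwissen & Luo's
    algorithm unrolls): F_i equals the kinship of the parents.
    """
    s, d = pedigree.sire, pedigree.dam
    F = np.zeros(pedigree.n)
    memo: dict[tuple[int, int], float] = {}

    def kin(i: int, j: int) -> float:
        if i < 0 or j < 0:
            return 0.0
        if j > i:
            i, j = j, i
        key = (i, j)
        val = memo.get(key)
        if val is not None:
            return val
        if i == j:
            val = 0.5 * (1.0 + kin(s[i], d[i]))
        else:
            val = 0.5 * (kin(s[i], j) + kin(d[i], j))
        memo[key] = val
        return val

    import sys

    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, pedigree.n * 4 + 100))
    try:
        for i in range(pedigree.n):
            F[i] = kin(s[i], d[i])
    finally:
        sys.setrecursionlimit(old)
    return F


def nrm_inverse(pedigree: Pedigree, return_triplets: bool = False):
    """Direct inverse of A via Henderson's rules with inbreeding.

    The Mendelian sampling variance of animal i is
    m_i = 0.5 - 0.25 (F_s + F_d) (both parents known),
    0.75 - 0.25 F_p (one parent), 1 (none); A⁻¹ accumulates
    alpha = 1/m_i at (i,i), -alpha/2 at (i, parent) and alpha/4 between
    known parents.
    """
    n = pedigree.n
    F = inbreeding(pedigree)
    s, d = pedigree.sire, pedigree.dam

    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []

    def add(r, c, v):
        rows.append(np.asarray(r))
        cols.append(np.asarray(c))
        vals.append(np.asarray(v, dtype=float))

    Fs = np.where(s >= 0, F[np.maximum(s, 0)], 0.0)
    Fd = np.where(d >= 0, F[np.maximum(d, 0)], 0.0)
    both = (s >= 0) & (d >= 0)
    one = (s >= 0) ^ (d >= 0)
    m = np.where(both, 0.5 - 0.25 * (Fs + Fd), np.where(one, 0.75 - 0.25 * (Fs + Fd), 1.0))
    alpha = 1.0 / m
    i_all = np.arange(n)
    add(i_all, i_all, alpha)
    for par in (s, d):
        k = par >= 0
        add(i_all[k], par[k], -alpha[k] / 2.0)
        add(par[k], i_all[k], -alpha[k] / 2.0)
        add(par[k], par[k], alpha[k] / 4.0)
    k = both
    add(s[k], d[k], alpha[k] / 4.0)
    add(d[k], s[k], alpha[k] / 4.0)

    r = np.concatenate(rows)
    c = np.concatenate(cols)
    v = np.concatenate(vals)
    if return_triplets:
        return r, c, v
    Ainv = np.zeros((n, n))
    np.add.at(Ainv, (r, c), v)
    return Ainv


def a22(pedigree: Pedigree, genotyped_ids: Iterable[str], A: np.ndarray | None = None) -> np.ndarray:
    """A restricted to genotyped animals (direct dense subset)."""
    idx = pedigree.indices(genotyped_ids)
    if A is None:
        A = nrm(pedigree).matrix
    return A[np.ix_(idx, idx)].copy()
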