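"""Optimal non-overlapping sphere cover of mutation counts.

Given per-residue mutation counts and a radius r, find the s spheres
(s = 1, 2 or 3; centers restricted to residue α-carbons) that jointly cover
the largest number of mutation occurrences, subject to the constraint that
sphere centers are at least 2r apart (non-overlapping balls, tangency
allowed).  Candidate centers are ALL residues, not only mutated ones.

The search sorts candidate centers by their individual coverage and runs a
best-first traversal of the strictly-decreasing index lattice: the element
(i1 > i2 > ... > is) has priority c[i1] + ... + c[is], an upper bound on the
union coverage of the corresponding configuration.  Elements are popped in
non-increasing priority; the first popped element whose centers are pairwise
>= 2r apart is a global optimum, because every element not yet popped has
priority (hence union coverage) no larger.  Worst case the traversal visits
all C(N, s) subsets — the same as brute force — but with small radii the
first feasible element is found after very few pops.
"""

from __future__ import annotations

import heapq
import itertools
import math
from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .geometry import StructureModel
from .mutmap import MutationTally


class BruteForceGuardError(ValueError):
    """Refusal to enumerate an exhaustive search space that is too large."""


@dataclass(frozen=True)
class CoverageVector:
    """Per-center coverage c[i] = total mutations within radius r of residue i,
    plus the candidate order sorted by coverage (descending, ties by ascending
    residue index)."""

    c: np.ndarray
    order: np.ndarray

    def __post_init__(self):
        assert len(self.c) == len(self.order)


@dataclass(frozen=True)
class CandidateElement:
    """A point of the search lattice: ``centers`` are indices into the sorted
    candidate order, strictly decreasing; ``priority`` is the sum of their
    individual coverages (an upper bound on the union coverage)."""

    centers: tuple[int, ...]
    priority: int


@dataclass(frozen=True)
class SphereConfiguration:
    """s spheres of common radius r with their covered-mutation count.

    ``centers`` are 1-based residue indices (ascending); ``covered`` is the
    number of mutation occurrences in the union of the s closed balls;
    ``members`` are the per-sphere residue index sets.  ``feasible`` is False
    when no pairwise non-overlapping configuration exists at all (the cell is
    then excluded downstream).
    """

    s: int
    r: float
    centers: tuple[int, ...]
    covered: int
    members: tuple[frozenset[int], ...]
    feasible: bool = True

    def to_dict(self, model: StructureModel | None = None) -> dict:
        def label(i: int):
            return model.residues[i - 1].structure_position if model else i

        return {
            "s": self.s,
            "r": self.r,
            "feasible": self.feasible,
            "centers": [label(i) for i in self.centers],
            "covered": self.covered,
            "members": [sorted(label(i) for i in m) for m in self.members],
        }


def search_space_size(n_residues: int, s: int) -> int:
    """Number of candidate s-sphere center sets on an N-residue protein,
    ignoring the overlap constraint: C(N, s)."""
    return math.comb(n_residues, s)


def _counts_array(tally: MutationTally | np.ndarray) -> np.ndarray:
    if isinstance(tally, MutationTally):
        return tally.structure_counts
    return np.asarray(tally, dtype=np.int64)


def coverage_vector(
    model: StructureModel, tally: MutationTally | np.ndarray, r: float
) -> CoverageVector:
    """Coverage of the single sphere centered at each residue, with the
    deterministic candidate order (coverage descending, index ascending)."""
    counts = _counts_array(tally)
    c = model.neighbor_matrix(r) @ counts
    order = np.lexsort((np.arange(len(c)), -c))
    return CoverageVector(c=c, order=order)


def iter_candidates(sorted_coverage: np.ndarray, s: int) -> Iterator[CandidateElement]:
    """Yield lattice elements in non-increasing priority.

    ``sorted_coverage`` is the coverage vector already in candidate order
    (descending).  Elements are tuples of s indices into that order, strictly
    decreasing; the first yield is the top element ((1, 0) for s = 2,
    (2, 1, 0) for s = 3).  Ties are yielded smallest-tuple first.
    """
    n = len(sorted_coverage)
    if s < 1 or n < s:
        return
    seed = tuple(range(s - 1, -1, -1))
    heap = [(-int(sorted_coverage[list(seed)].sum()), seed)]
    visited = {seed}
    last = None
    while heap:
        negp, centers = heapq.heappop(heap)
        assert last is None or -negp <= last, "pop priorities must be non-increasing"
        last = -negp
        yield CandidateElement(centers=centers, priority=-negp)
        for k in range(s):
            nxt = centers[k] + 1
            if nxt >= n or (k > 0 and nxt >= centers[k - 1]):
                continue
            succ = centers[:k] + (nxt,) + centers[k + 1 :]
            if succ not in visited:
                visited.add(succ)
                delta = int(sorted_coverage[nxt] - sorted_coverage[centers[k]])
                heapq.heappush(heap, (negp - delta, succ))


def _union_covered(M: np.ndarray, counts: np.ndarray, centers: np.ndarray) -> int:
    mask = M[centers].any(axis=0)
    return int(counts[mask].sum())


def _admissible(Dok: np.ndarray, centers, s: int) -> bool:
    if s == 2:
        return bool(Dok[centers[0], centers[1]])
    if s == 3:
        return bool(
            Dok[centers[0], centers[1]]
            and Dok[centers[0], centers[2]]
            and Dok[centers[1], centers[2]]
        )
    return all(
        Dok[centers[a], centers[b]] for a in range(s) for b in range(a + 1, s)
    )


def _search(
    counts: np.ndarray,
    M: np.ndarray,
    Dok: np.ndarray,
    s: int,
    order: np.ndarray | None = None,
    c: np.ndarray | None = None,
) -> tuple[np.ndarray, int] | None:
    """Best-first search kernel.

    ``Dok`` is the boolean admissibility matrix (center distance >= 2r).
    Returns (0-based centers, union covered) or None when no non-overlapping
    configuration exists.  Mirrors :func:`iter_candidates` but inlined (plain
    tuples, seed checked before the heap exists) for the simulation loop.
    """
    if c is None:
        c = M @ counts
    if order is None:
        order = np.argsort(-c, kind="stable")
    if s == 1:
        best = int(order[0])
        return order[:1], int(c[best])
    n = len(c)
    if n < s:
        return None
    # Fast path: the top-s candidates, the lattice seed. Usually admissible.
    seed = tuple(range(s - 1, -1, -1))
    top = order[list(seed)]
    if _admissible(Dok, top, s):
        return top, _union_covered(M, counts, top)
    csort = c[order]
    heap: list[tuple[int, tuple[int, ...]]] = []
    visited = {seed}
    negp0 = -int(csort[:s].sum())

    def push_successors(negp: int, centers: tuple[int, ...]):
        for k in range(s):
            nxt = centers[k] + 1
            if nxt >= n or (k > 0 and nxt >= centers[k - 1]):
                continue
            succ = centers[:k] + (nxt,) + centers[k + 1 :]
            if succ not in visited:
                visited.add(succ)
                delta = int(csort[nxt] - csort[centers[k]])
                heapq.heappush(heap, (negp - delta, succ))

    push_successors(negp0, seed)
    while heap:
        negp, elem = heapq.heappop(heap)
        centers = order[list(elem)]
        if _admissible(Dok, centers, s):
            return centers, _union_covered(M, counts, centers)
        push_successors(negp, elem)
    return None


def _config_from(
    model: StructureModel, s: int, r: float, found: tuple[np.ndarray, int] | None
) -> SphereConfiguration:
    if found is None:
        return SphereConfiguration(
            s=s, r=r, centers=(), covered=0, members=(), feasible=False
        )
    centers0, covered = found
    centers = tuple(sorted(int(i) + 1 for i in centers0))
    members = tuple(model.neighborhood(ctr, r) for ctr in centers)
    return SphereConfiguration(
        s=s, r=r, centers=centers, covered=covered, members=members
    )


def best_spheres(
    model: StructureModel, tally: MutationTally | np.ndarray, s: int, r: float
) -> SphereConfiguration:
    """Globally optimal s non-overlapping spheres of radius r (best-first).

    The returned ``covered`` equals the maximum union coverage over all
    s-subsets of residue centers with pairwise center distance >= 2r.  Ties
    are broken toward the configuration found first in the deterministic
    traversal order (largest priority, then lexicographically smallest tuple
    of sorted-order indices).
    """
    if s < 1:
        raise ValueError("s must be >= 1")
    counts = _counts_array(tally)
    found = _search(
        counts, model.neighbor_matrix(r), model.distance_matrix >= 2.0 * r, s
    )
    return _config_from(model, s, r, found)


def brute_force_spheres(
    model: StructureModel,
    tally: MutationTally | np.ndarray,
    s: int,
    r: float,
    max_residues: int = 50,
) -> SphereConfiguration:
    """Exhaustive-enumeration oracle for :func:`best_spheres` (testing only).

    Maximizes union coverage over all non-overlapping s-subsets; ties broken
    by lexicographically smallest center tuple.  Guarded to small structures.
    """
    if model.N > max_residues:
        raise BruteForceGuardError(
            f"brute force refused for N={model.N} > {max_residues}"
        )
    counts = _counts_array(tally)
    M = model.neighbor_matrix(r)
    D = model.distance_matrix
    two_r = 2.0 * r
    best: tuple[np.ndarray, int] | None = None
    for combo in itertools.combinations(range(model.N), s):
        if any(D[a, b] < two_r for a, b in itertools.combinations(combo, 2)):
            continue
        covered = _union_covered(M, counts, np.array(combo))
        if best is None or covered > best[1]:
            best = (np.array(combo), covered)
    return _config_from(model, s, r, best)
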