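"""Ternary sign-pattern machinery.

The interaction *type* between taxa is the sign of a Jacobian entry of the
(unknown) population dynamics: ``+`` promotion, ``-`` inhibition, ``0`` no
direct interaction.  Under a constant Jacobian sign-pattern, the sign row
``s_i`` of taxon *i* must be realizable by a real vector orthogonal to every
difference of two steady-state samples that share taxon *i*.  This module
provides that feasibility test in two equivalent forms — a direct O(N)
combinatorial test and a linear-programming oracle — plus the brute-force
enumeration of all admissible sign rows and the prior-based resolution step.

Sign patterns are plain integer vectors over {-1, 0, +1}; candidate sets are
Python sets of tuples so they hash and compare cheaply.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .samples import SampleSet

__all__ = [
    "SignMatrix",
    "CandidateSet",
    "LPSolverError",
    "sign_of",
    "sign_satisfies",
    "lp_feasible",
    "enumerate_patterns",
    "pairwise_differences",
    "admissible_patterns_bruteforce",
    "resolve_signs",
]

#: brute-force enumeration refuses above this community size (3^N blow-up)
MAX_BRUTEFORCE_TAXA = 12

#: strict-inequality margin used when encoding open sign constraints in the LP
LP_EPS = 1e-6


class LPSolverError(RuntimeError):
    """The LP solver failed for a reason other than plain infeasibility."""


def sign_of(v, tol: float = 0.0) -> np.ndarray:
    """Ternary sign vector of ``v``; entries with ``|v_j| <= tol`` become 0."""
    if tol < 0:
        raise ValueError("tol must be non-negative")
    v = np.asarray(v, dtype=float)
    out = np.sign(v).astype(np.int8)
    out[np.abs(v) <= tol] = 0
    return out


def sign_satisfies(s, w, tol: float = 0.0) -> bool:
    """Is there a real vector with sign-pattern ``s`` orthogonal to ``w``?

    Equivalently: does the hyperplane through the origin with normal ``w``
    cross the (possibly degenerate) orthant described by ``s``?  The direct
    characterization: with p_j = s_j * w_j, feasibility holds iff either all
    p_j vanish (the orthant lies inside the hyperplane) or the products take
    both signs, so positive and negative contributions can be balanced by
    choosing magnitudes.
    """
    s = np.asarray(s)
    w = np.asarray(w, dtype=float)
    if s.shape != w.shape:
        raise ValueError("sign-pattern and vector lengths differ")
    w = np.where(np.abs(w) <= tol, 0.0, w)
    p = s * w
    has_pos = bool(np.any(p > 0))
    has_neg = bool(np.any(p < 0))
    return has_pos == has_neg


def lp_feasible(s, w, eps: float = LP_EPS) -> bool:
    """LP oracle for :func:`sign_satisfies`.

    Searches for ``v`` in the unit box with ``v . w = 0`` and ``sign(v) = s``,
    encoding the open constraints ``v_j > 0`` as ``v_j >= eps`` (and mirrored
    for negative signs).  Must agree with :func:`sign_satisfies` on every
    input; kept as the independent reference implementation.
    """
    s = np.asarray(s)
    w = np.asarray(w, dtype=float)
    if s.shape != w.shape:
        raise ValueError("sign-pattern and vector lengths differ")
    if eps <= 0:
        raise ValueError("eps must be positive")
    scale = np.abs(w).max()
    if scale > 0:
        w = w / scale  # unit max-abs so eps stays above solver tolerances
    bounds = []
    for sj in s:
        if sj > 0:
            bounds.append((eps, 1.0))
        elif sj < 0:
            bounds.append((-1.0, -eps))
        else:
            bounds.append((0.0, 0.0))
    res = linprog(
        c=np.zeros_like(w),
        A_eq=w.reshape(1, -1),
        b_eq=[0.0],
        bounds=bounds,
        method="highs",
        options={
            "primal_feasibility_tolerance": 1e-10,
            "dual_feasibility_tolerance": 1e-10,
        },
    )
    if res.status == 0:
        return True
    if res.status == 2:  # proven infeasible
        return False
    raise LPSolverError(f"linprog failed with status {res.status}: {res.message}")


def enumerate_patterns(n_taxa: int):
    """Yield all 3**N ternary patterns of length ``n_taxa`` as int8 arrays."""
    for combo in itertools.product((-1, 0, 1), repeat=n_taxa):
        yield np.array(combo, dtype=np.int8)


@dataclass
class CandidateSet:
    """Admissible sign-patterns for one taxon row.

    Always contains the all-zero pattern and is closed under negation.  The
    data pin the row down completely exactly when three patterns remain
    (``{-a, 0, a}``); the sign of any single non-zero entry then picks ``a``.
    ``unidentified`` marks coordinates the data carry no information about
    (taxa never observed to vary alongside the focal taxon); they are always
    resolved as undetermined.
    """

    patterns: set[tuple[int, ...]]
    taxon: int
    unidentified: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        self.patterns = {tuple(int(x) for x in p) for p in self.patterns}
        self.unidentified = frozenset(self.unidentified)

    @property
    def n_taxa(self) -> int:
        return len(next(iter(self.patterns)))

    @property
    def informative(self) -> bool:
        return len(self.patterns) == 3

    def __len__(self) -> int:
        return len(self.patterns)

    def __contains__(self, pattern) -> bool:
        return tuple(int(x) for x in np.asarray(pattern)) in self.patterns


#: entries of a difference vector below this fraction of its largest entry
#: are snapped to exact zero (numerically-integrated steady states carry
#: residuals ~1e-7 that would otherwise fake tiny sign constraints)
DIFF_REL_TOL = 1e-5


def pairwise_differences(
    samples: SampleSet, taxon: int, rel_tol: float = DIFF_REL_TOL
) -> np.ndarray:
    """All vectors ``x^I - x^K`` over unordered pairs of samples sharing ``taxon``.

    Returns an ``(n_pairs, N)`` array (row-per-difference orientation).
    Entries smaller than ``rel_tol`` times the row's max-abs entry are set to
    zero so that integration residuals cannot masquerade as constraints.
    """
    shared = samples.samples_with_taxon(taxon)
    if shared.shape[0] == 0:
        raise ValueError(f"taxon {taxon} is absent from every sample")
    idx_a, idx_b = np.triu_indices(shared.shape[0], k=1)
    diffs = shared[idx_a] - shared[idx_b]
    scale = np.abs(diffs).max(axis=1, keepdims=True)
    diffs[np.abs(diffs) <= rel_tol * scale] = 0.0
    return diffs


def admissible_patterns_bruteforce(
    samples: SampleSet,
    taxon: int,
    max_taxa: int = MAX_BRUTEFORCE_TAXA,
) -> CandidateSet:
    """Enumerate every sign-pattern admissible for the row of ``taxon``.

    A pattern is admissible when it sign-satisfies *all* pairwise sample
    differences among samples containing the taxon.  Exponential in N; refuses
    above ``max_taxa`` (raise the limit explicitly to override).
    """
    n = samples.n_taxa
    if n > max_taxa:
        raise ValueError(
            f"brute-force enumeration over 3^{n} patterns refused "
            f"(limit {max_taxa}); use the heuristic or raise max_taxa"
        )
    diffs = pairwise_differences(samples, taxon)
    kept: set[tuple[int, ...]] = set()
    for s in enumerate_patterns(n):
        p = diffs * s  # (n_pairs, N) products
        pos = (p > 0).any(axis=1)
        neg = (p < 0).any(axis=1)
        if np.array_equal(pos, neg):  # every pair balanced or untouched
            kept.add(tuple(int(x) for x in s))
    return CandidateSet(patterns=kept, taxon=taxon)


@dataclass
class ResolvedRow:
    """Outcome of prior-based resolution for one taxon row."""

    signs: np.ndarray  # int8, meaningful only where determined
    determined: np.ndarray  # bool mask
    warning: str | None = None


def resolve_signs(candidates: CandidateSet, prior: dict[int, int] | None = None) -> ResolvedRow:
    """Pick the sign row from a candidate set using prior sign knowledge.

    ``prior`` maps taxon index -> known sign; the default pins the intra-taxon
    term negative (self-regulation, generally required for stability).
    Candidates inconsistent with the prior are dropped; each entry is then
    fixed where all surviving non-zero candidates agree, otherwise marked
    undetermined.
    """
    if not candidates.patterns:
        raise ValueError("empty candidate set")
    n = candidates.n_taxa
    if prior is None:
        prior = {candidates.taxon: -1}
    survivors = [
        p
        for p in candidates.patterns
        if any(p) and all(p[j] == sgn for j, sgn in prior.items())
    ]
    signs = np.zeros(n, dtype=np.int8)
    determined = np.zeros(n, dtype=bool)
    if not survivors:
        return ResolvedRow(
            signs,
            determined,
            warning="no candidate sign-pattern is consistent with the prior",
        )
    arr = np.array(survivors, dtype=np.int8)
    agree = (arr == arr[0]).all(axis=0)
    signs[agree] = arr[0][agree]
    determined[agree] = True
    for j in candidates.unidentified:
        determined[j] = False
        signs[j] = 0
    return ResolvedRow(signs, determined)


@dataclass
class SignMatrix:
    """N x N ternary interaction-type matrix with an undetermined marker."""

    values: np.ndarray  # int8; meaningful only where determined
    determined: np.ndarray  # bool mask
    taxon_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        self.determined = np.asarray(self.determined, dtype=bool)
        if self.values.shape != self.determined.shape:
            raise ValueError("values/determined shape mismatch")
        if not self.taxon_ids:
            self.taxon_ids = [f"taxon_{j + 1}" for j in range(self.values.shape[1])]

    @classmethod
    def from_values(cls, values, taxon_ids: list[str] | None = None) -> "SignMatrix":
        values = np.asarray(values)
        return cls(
            values=values.astype(np.int8),
            determined=np.ones(values.shape, dtype=bool),
            taxon_ids=taxon_ids or [],
        )

    @property
    def n_taxa(self) -> int:
        return self.values.shape[0]

    def to_dataframe(self) -> pd.DataFrame:
        obj = self.values.astype(object)
        obj[~self.determined] = "NA"
        return pd.DataFrame(obj, index=self.taxon_ids, columns=self.taxon_ids)
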