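"""Scalable heuristic sign-pattern inference.

The brute-force enumeration of admissible sign rows is exponential in the
number of taxa.  The heuristic sidesteps it geometrically: every pairwise
difference of samples sharing taxon *i* defines a hyperplane through the
origin that the true sign row must be able to cross.  Any N-1 of those
hyperplanes generically intersect in a line; the sign-pattern of that line is
a candidate row, and the fraction phi of *all* difference hyperplanes that
cross its (three) orthants measures its confidence.  Drawing Psi random
intersection lines and keeping the best-scoring pattern yields the candidate
set ``{-a, 0, a}`` without ever touching the 3^N solution space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .samples import SampleSet
from .signs import (
    CandidateSet,
    ResolvedRow,
    SignMatrix,
    admissible_patterns_bruteforce,
    resolve_signs,
    sign_of,
)

__all__ = [
    "DifferenceMatrix",
    "ScoredLine",
    "InferenceReport",
    "build_difference_matrix",
    "sample_intersection_line",
    "score_line",
    "heuristic_infer_row",
    "infer_sign_matrix",
]

#: default number of intersection lines per row, as a multiple of N
DEFAULT_PSI_FACTOR = 5

#: retries per requested line when sampled hyperplanes fail to meet in a line
RETRY_BUDGET = 50

#: a null space is "a line" when exactly one singular value falls below
#: RANK_TOL_RATIO times the largest one
RANK_TOL_RATIO = 1e-10

#: zero threshold on max-abs-normalized line directions: when the difference
#: hyperplanes are not exactly orthogonal to a single constant row (saturating
#: dynamics, measurement noise), truly-zero interactions show up as small but
#: non-zero direction entries.  0.5% of the leading entry sits above the bulk
#: of those spurious magnitudes (the cross-line consensus vote removes the
#: rest) while staying well below the weakest real interaction, whose
#: relative magnitude is ~0.2/N under 1/N-scaled interaction strengths
DIRECTION_ZERO_TOL = 0.005


@dataclass
class DifferenceMatrix:
    """All pairwise sample differences for one taxon row.

    ``diffs`` holds one difference ``x^I - x^K`` per row, for every unordered
    pair of samples whose supports contain ``taxon``.  ``active`` lists the
    coordinates that actually vary across those samples; a taxon that never
    co-occurs with (or never varies alongside) the focal taxon contributes an
    identically-zero column, carries no information about its interaction,
    and is excluded from the line geometry.
    """

    diffs: np.ndarray  # (n_pairs, N)
    taxon: int
    pair_index: list[tuple[int, int]]
    active: np.ndarray = None  # indices of non-degenerate columns

    def __post_init__(self) -> None:
        if self.active is None:
            self.active = np.flatnonzero(np.any(self.diffs != 0, axis=0))

    @property
    def n_pairs(self) -> int:
        return self.diffs.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.diffs.shape[1]

    @property
    def unidentified(self) -> frozenset[int]:
        """Coordinates with no data: their interaction signs are undecidable."""
        return frozenset(set(range(self.n_taxa)) - set(self.active.tolist()))


@dataclass
class ScoredLine:
    direction: np.ndarray  # normalized to unit max-abs entry
    pattern: np.ndarray  # int8 ternary
    phi: float
    #: coordinates the line carries no information about (degenerate columns
    #: not resolved by this draw); undetermined after resolution
    unidentified: frozenset[int] = frozenset()


def build_difference_matrix(samples: SampleSet, taxon: int) -> DifferenceMatrix:
    """Stack ``x^I - x^K`` for all unordered pairs of samples sharing ``taxon``."""
    shared = samples.samples_with_taxon(taxon)
    if shared.shape[0] < 2:
        raise ValueError(
            f"need at least 2 samples containing taxon {taxon}, "
            f"got {shared.shape[0]}"
        )
    idx_a, idx_b = np.triu_indices(shared.shape[0], k=1)
    diffs = shared[idx_a] - shared[idx_b]
    scale = np.abs(diffs).max(axis=1, keepdims=True)
    diffs[np.abs(diffs) <= 1e-5 * scale] = 0.0  # drop integration residuals
    norms = np.abs(diffs).max(axis=1)
    if np.any(norms <= samples.zero_tol):
        raise ValueError(
            "identical samples with the same support; average replicates first"
        )
    return DifferenceMatrix(
        diffs=diffs,
        taxon=taxon,
        pair_index=list(zip(idx_a.tolist(), idx_b.tolist())),
    )


def sample_intersection_line(
    M: DifferenceMatrix,
    rng: np.random.Generator,
    zero_tol: float = DIRECTION_ZERO_TOL,
) -> ScoredLine | None:
    """Draw N-1 difference hyperplanes and intersect them into a line.

    Returns ``None`` (caller retries) when the sampled hyperplanes do not
    intersect in a line, i.e. the stacked differences have a null space of
    dimension other than one.  With fewer than N-1 available differences all
    of them are used and an arbitrary kernel basis vector is returned.

    Coordinates whose difference column is identically zero (taxa that never
    vary across the samples sharing the focal taxon) are handled separately,
    since they put a basis vector ``e_j`` into every null space: if the
    remaining coordinates are fully spanned by the differences, the
    intersection line *is* such an ``e_j`` (e.g. an isolated focal taxon
    whose abundance never changes); if instead they leave a one-dimensional
    kernel, that reduced kernel is the line and the zero-column coordinates
    are reported as unidentifiable.
    """
    n = M.n_taxa
    active = M.active
    zero_cols = sorted(M.unidentified)
    m = len(active)
    if m < 2:
        return None
    k = min(n - 1, M.n_pairs)
    rows = rng.choice(M.n_pairs, size=k, replace=False)
    stack = M.diffs[np.ix_(rows, active)]
    _, svals, vt = np.linalg.svd(stack)
    rank = int(np.sum(svals > RANK_TOL_RATIO * svals[0]))
    reduced_nullity = m - rank
    direction = np.zeros(n)
    unidentified: frozenset[int] = frozenset()
    if reduced_nullity == 0:
        if not zero_cols:
            return None
        # differences span the whole active subspace: the line is along a
        # degenerate coordinate (no interactions reach it through the data)
        direction[zero_cols[0]] = 1.0
        unidentified = frozenset(zero_cols[1:])
    elif reduced_nullity == 1 or M.n_pairs < n - 1:
        # a unique line, or an under-determined draw (fewer differences than
        # N-1 available): take a kernel basis vector either way
        direction[active] = vt[-1]
        unidentified = frozenset(zero_cols)
    else:
        return None
    direction = direction / np.abs(direction).max()
    # canonical orientation so identical lines hash identically
    lead = direction[np.flatnonzero(np.abs(direction) > zero_tol)[0]]
    if lead < 0:
        direction = -direction
    pattern = sign_of(direction, tol=zero_tol)
    return ScoredLine(
        direction=direction, pattern=pattern, phi=np.nan,
        unidentified=unidentified,
    )


def score_line(line: ScoredLine, M: DifferenceMatrix) -> float:
    """Fraction of all difference hyperplanes crossing the line's orthants.

    phi = 1 means the candidate sign-pattern is sign-satisfiable against every
    pairwise difference; phi is the confidence that the line is the true row.
    """
    p = M.diffs * line.pattern
    pos = (p > 0).any(axis=1)
    neg = (p < 0).any(axis=1)
    return float(np.mean(pos == neg))


#: consensus is taken over this top fraction of lines ranked by phi
CONSENSUS_FRACTION = 0.25

#: an entry gets a non-zero consensus sign only when the phi-weighted vote
#: for that sign exceeds this fraction of the total weight (strict majority)
CONSENSUS_MAJORITY = 0.5


def _consensus_pattern(lines: list[ScoredLine]) -> np.ndarray:
    """Per-entry phi-weighted sign vote over the best-scoring lines.

    Line directions are defined only up to a global sign, so each is first
    oriented toward the top line.  Entries whose ternary signs agree across
    the high-confidence lines keep that sign; entries without a strict
    weighted majority (sign flips across lines: spurious, noise-driven
    coordinates) are set to zero.  Selecting a single maximal-phi line
    instead is biased toward dense patterns, because a pattern with more
    non-zero entries sign-satisfies hyperplanes more easily.
    """
    ranked = sorted(lines, key=lambda l: -l.phi)
    keep = ranked[: max(1, int(len(ranked) * CONSENSUS_FRACTION))]
    ref = keep[0].direction
    votes = np.zeros(len(ref))
    total = 0.0
    for line in keep:
        aligned = line.pattern if line.direction @ ref >= 0 else -line.pattern
        votes += line.phi * aligned
        total += line.phi
    return sign_of(votes, tol=CONSENSUS_MAJORITY * total)


def heuristic_infer_row(
    samples: SampleSet,
    taxon: int,
    psi: int | None = None,
    rng: np.random.Generator | None = None,
    retry_budget: int = RETRY_BUDGET,
    zero_tol: float = DIRECTION_ZERO_TOL,
) -> tuple[CandidateSet, float, list[ScoredLine]]:
    """Infer the candidate sign set for one taxon row from Psi scored lines.

    Draws ``psi`` intersection lines (default 5N), scores each by phi, and
    forms the candidate set ``{-a, 0, a}`` from the phi-weighted per-entry
    consensus over the top-scoring lines (see :func:`_consensus_pattern`).
    The returned phi is the best score observed and acts as the row's
    confidence.
    """
    if rng is None:
        rng = np.random.default_rng()
    n = samples.n_taxa
    if psi is None:
        psi = DEFAULT_PSI_FACTOR * n
    if psi < 1:
        raise ValueError("psi must be >= 1")
    M = build_difference_matrix(samples, taxon)
    lines: list[ScoredLine] = []
    for _ in range(psi):
        line = None
        for _ in range(retry_budget):
            line = sample_intersection_line(M, rng, zero_tol=zero_tol)
            if line is not None:
                break
        if line is None:
            continue  # budget exhausted for this draw; skip it
        line.phi = score_line(line, M)
        lines.append(line)
    if not lines:
        raise ValueError(
            f"no intersection line found for taxon {taxon} within the retry budget"
        )
    best_phi = max(line.phi for line in lines)
    consensus = _consensus_pattern(lines)
    patterns: set[tuple[int, ...]] = {tuple(np.zeros(n, dtype=int))}
    if consensus.any():
        patterns.add(tuple(int(v) for v in consensus))
        patterns.add(tuple(-int(v) for v in consensus))
    # structurally-dataless coordinates stay unidentifiable unless the
    # consensus line itself resolves them (isolated-taxon case)
    consensus_support = {int(j) for j in np.flatnonzero(consensus)}
    cand = CandidateSet(
        patterns=patterns,
        taxon=taxon,
        unidentified=frozenset(M.unidentified - consensus_support),
    )
    return cand, best_phi, lines


@dataclass
class InferenceReport:
    """Provenance and per-row summaries of a sign-matrix inference run."""

    method: str
    seed: int | None
    psi: int | None
    rows: dict[int, dict] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "seed": self.seed,
            "psi": self.psi,
            "rows": {str(k): v for k, v in self.rows.items()},
            "warnings": self.warnings,
        }


def infer_sign_matrix(
    samples: SampleSet,
    method: str = "heuristic",
    priors: dict[tuple[int, int], int] | None = None,
    psi: int | None = None,
    seed: int | None = None,
    max_bruteforce_taxa: int = 12,
    check_assumptions: bool = True,
    line_zero_tol: float | None = None,
) -> tuple[SignMatrix, InferenceReport]:
    """Row-by-row interaction-type inference over all taxa.

    Runs the compositionality and true-multistability guards, infers each
    row's candidate set (brute-force enumeration or heuristic lines), and
    resolves it against the priors (default: negative self-regulation,
    ``s_ii = -``).  Rows that fail are reported undetermined, not fatal.
    """
    if method not in ("bruteforce", "heuristic"):
        raise ValueError(f"unknown method {method!r}")
    if check_assumptions:
        from . import diagnostics  # deferred: diagnostics imports this module

        flagged, _ = diagnostics.compositionality_guard(samples)
        if flagged:
            raise ValueError(
                "samples look compositional (all row sums equal): sign "
                "inference from relative abundances is ill-posed — every "
                "intersection line degenerates to the all-ones direction; "
                "provide absolute abundances"
            )
        multi, groups = diagnostics.detect_true_multistability(samples)
        if multi:
            raise ValueError(
                "true multi-stability detected (same support, different "
                f"steady states: {groups}); the constant sign-pattern "
                "assumption fails, so only the zero-pattern may be inferred"
            )
    rng = np.random.default_rng(seed)
    n = samples.n_taxa
    priors = priors or {}
    values = np.zeros((n, n), dtype=np.int8)
    determined = np.zeros((n, n), dtype=bool)
    report = InferenceReport(method=method, seed=seed, psi=psi)
    for i in range(n):
        row_prior = {j: s for (pi, j), s in priors.items() if pi == i}
        row_prior.setdefault(i, -1)
        row_info: dict = {"prior": {str(k): int(v) for k, v in row_prior.items()}}
        try:
            if method == "bruteforce":
                cand = admissible_patterns_bruteforce(
                    samples, i, max_taxa=max_bruteforce_taxa
                )
                row_info["n_candidates"] = len(cand)
            else:
                cand, phi, lines = heuristic_infer_row(
                    samples, i, psi=psi, rng=rng,
                    zero_tol=(
                        line_zero_tol
                        if line_zero_tol is not None
                        else DIRECTION_ZERO_TOL
                    ),
                )
                row_info["phi"] = phi
                row_info["n_candidates"] = len(cand)
                row_info["n_lines"] = len(lines)
        except ValueError as exc:
            report.warnings.append(f"row {i}: {exc}")
            row_info["error"] = str(exc)
            report.rows[i] = row_info
            continue
        resolved: ResolvedRow = resolve_signs(cand, prior=row_prior)
        if resolved.warning:
            report.warnings.append(f"row {i}: {resolved.warning}")
            row_info["warning"] = resolved.warning
        values[i] = resolved.signs
        determined[i] = resolved.determined
        row_info["n_undetermined"] = int((~resolved.determined).sum())
        report.rows[i] = row_info
    matrix = SignMatrix(
        values=values, determined=determined, taxon_ids=list(samples.taxon_ids)
    )
    return matrix, report
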