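"""Assumption checks and evaluation metrics.

Two guards protect the inference's assumptions: the *true multistability*
detector (two samples on the same support with different abundances falsify
the constant Jacobian sign-pattern assumption) and the *compositionality*
guard (relative-abundance tables, whose unit row sums make every pairwise
difference orthogonal to the all-ones vector and defeat sign inference).

The evaluation side scores inferred sign matrices against ground truth
(accuracy, FDR), scores inferred GLV parameters (NRMSE), measures robustness
of signs to measurement noise, and runs the minimal-sample-size experiment
underlying the linear Omega*(N) scaling analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .samples import SampleSet
from .signs import SignMatrix
from .simulate import (
    DynamicsModel,
    PresenceModel,
    generate_sample_set,
    jacobian_sign_truth,
    random_model,
)

__all__ = [
    "EvaluationResult",
    "detect_true_multistability",
    "compositionality_guard",
    "relative_yield",
    "predict_invasion_response",
    "sign_accuracy",
    "nrmse",
    "fdr_offdiagonal",
    "robustness_analysis",
    "plateau_accuracy_experiment",
    "min_sample_size_experiment",
]

#: same-support samples differing by more than this (relative L-inf) are
#: treated as genuinely distinct steady states
MULTISTABILITY_TOL = 0.05


@dataclass
class EvaluationResult:
    """Sign-inference scores against a ground-truth sign matrix.

    ``accuracy`` is the percentage of correct signs among *determined*
    entries; ``accuracy_overall`` counts undetermined entries as incorrect
    (percentage of all scored entries whose sign was correctly inferred).
    """

    accuracy: float
    accuracy_overall: float
    fdr: float
    n_determined: int
    n_undetermined: int
    n_correct: int


def detect_true_multistability(
    samples: SampleSet, tol: float = MULTISTABILITY_TOL
) -> tuple[bool, list[frozenset[int]]]:
    """Find supports carrying several genuinely different steady states.

    Returns ``(flag, offending_supports)``.  When flagged, the constant
    sign-pattern assumption is falsified and only the zero-pattern (network
    topology) should be inferred from these data.
    """
    groups: dict[frozenset[int], list[int]] = {}
    for k, supp in enumerate(samples.supports):
        groups.setdefault(supp, []).append(k)
    offending = []
    for supp, members in groups.items():
        if len(members) < 2:
            continue
        block = samples.abundances[members]
        scale = np.abs(block).max()
        if scale == 0:
            continue
        spread = (block.max(axis=0) - block.min(axis=0)).max() / scale
        if spread > tol:
            offending.append(supp)
    return bool(offending), offending


def compositionality_guard(
    samples: SampleSet, tol: float = 1e-6
) -> tuple[bool, str | None]:
    """Flag tables that look like relative abundances (constant row sums)."""
    sums = samples.abundances.sum(axis=1)
    if samples.n_samples == 1:
        return False, "single sample: compositionality undecidable"
    mean = sums.mean()
    if mean == 0:
        return False, None
    if np.all(np.abs(sums - mean) <= tol * abs(mean)):
        return True, None
    return False, None


def relative_yield(
    mono: SampleSet, duo: SampleSet, i: int, j: int
) -> float:
    """Relative yield ``R_ij = (x_i^{ij} - x_i^{i}) / (x_i^{ij} + x_i^{i})``.

    Pairwise-culture proxy of the ground-truth interaction sign of taxon ``j``
    on taxon ``i``: negative means growth hindrance, positive facilitation.
    Requires a monoculture sample with support ``{i}`` in ``mono`` and a
    co-culture sample with support ``{i, j}`` in ``duo``.
    """

    def _find(ss: SampleSet, support: frozenset[int]) -> np.ndarray:
        for k, supp in enumerate(ss.supports):
            if supp == support:
                return ss.abundances[k]
        raise ValueError(f"no sample with support {sorted(support)}")

    x_mono = _find(mono, frozenset({i}))[i]
    x_duo = _find(duo, frozenset({i, j}))[i]
    if x_mono <= 0 or x_duo <= 0:
        raise ValueError("taxon must be present in both samples")
    return float((x_duo - x_mono) / (x_duo + x_mono))


def predict_invasion_response(
    signs: SignMatrix, invader: int
) -> dict[int, int | None]:
    """Predicted abundance change of each resident when ``invader`` is added.

    The direct effect of adding taxon ``j`` on resident ``i`` follows the sign
    of ``J_ij``: +1 increase, -1 decrease, 0 no change, ``None`` where the
    sign is undetermined (unpredictable).  Indirect (network-mediated)
    effects are deliberately ignored.
    """
    out: dict[int, int | None] = {}
    for i in range(signs.n_taxa):
        if i == invader:
            continue
        if signs.determined[i, invader]:
            out[i] = int(signs.values[i, invader])
        else:
            out[i] = None
    return out


def sign_accuracy(
    inferred: SignMatrix,
    truth: SignMatrix,
    include_diagonal: bool = True,
) -> EvaluationResult:
    """Score an inferred sign matrix against the ground truth.

    Percentages are reported on the 0-100 scale.  FDR here is the fraction of
    inferred non-zero interactions that are truly zero, computed over
    determined off-diagonal entries.
    """
    if inferred.values.shape != truth.values.shape:
        raise ValueError("shape mismatch between inferred and truth matrices")
    n = inferred.n_taxa
    scored = np.ones((n, n), dtype=bool)
    if not include_diagonal:
        np.fill_diagonal(scored, False)
    det = inferred.determined & scored
    correct = det & (inferred.values == truth.values)
    n_det = int(det.sum())
    n_undet = int((scored & ~inferred.determined).sum())
    n_correct = int(correct.sum())
    accuracy = 100.0 * n_correct / n_det if n_det else 0.0
    total = int(scored.sum())
    accuracy_overall = 100.0 * n_correct / total if total else 0.0
    offdiag = det.copy()
    np.fill_diagonal(offdiag, False)
    claimed = offdiag & (inferred.values != 0)
    false_pos = claimed & (truth.values == 0)
    fdr = float(false_pos.sum() / claimed.sum()) if claimed.sum() else 0.0
    return EvaluationResult(
        accuracy=accuracy,
        accuracy_overall=accuracy_overall,
        fdr=fdr,
        n_determined=n_det,
        n_undetermined=n_undet,
        n_correct=n_correct,
    )


def fdr_offdiagonal(
    A_hat: np.ndarray, A_true: np.ndarray, zero_tol: float = 1e-10
) -> float:
    """Matrix-wide FDR of inferred interaction strengths.

    Fraction of off-diagonal entries inferred non-zero whose true strength is
    exactly zero; 0 when nothing is inferred non-zero.
    """
    n = A_hat.shape[0]
    off = ~np.eye(n, dtype=bool)
    claimed = off & (np.abs(A_hat) > zero_tol)
    if not claimed.any():
        return 0.0
    false_pos = claimed & (A_true == 0)
    return float(false_pos.sum() / claimed.sum())


def nrmse(
    A_hat: np.ndarray,
    A_true: np.ndarray,
    r_hat: np.ndarray | None = None,
    r_true: np.ndarray | None = None,
) -> dict[str, float]:
    """Normalized root-mean-square errors of GLV parameter estimates.

    Range-normalized RMSE (the standard NRMSE): root-mean-square error over
    all matrix entries divided by the spread ``max - min`` of the true
    values, and the analogous ratio for the growth-rate vector when given.
    Range normalization keeps the metric meaningful when interaction
    strengths scale like 1/N while self-interactions stay O(1).
    """
    spread = float(A_true.max() - A_true.min())
    out = {
        "A": float(np.sqrt(np.mean((A_hat - A_true) ** 2)) / spread)
        if spread
        else np.nan
    }
    if r_hat is not None and r_true is not None:
        r_spread = float(r_true.max() - r_true.min())
        out["r"] = (
            float(np.sqrt(np.mean((r_hat - r_true) ** 2)) / r_spread)
            if r_spread
            else np.nan
        )
    return out


def robustness_analysis(
    samples: SampleSet,
    eta_grid,
    reps: int,
    infer_fn,
    rng: np.random.Generator | None = None,
) -> dict[float, np.ndarray]:
    """Per-entry sign stability under multiplicative measurement noise.

    ``infer_fn(SampleSet) -> SignMatrix``.  For each noise level eta, the
    samples are perturbed ``reps`` times and the fraction (percent) of
    realizations in which each inferred sign matches the noiseless inference
    is recorded.  Entries undetermined in a realization count as changed.
    """
    from .simulate import add_noise  # local to keep module deps one-way

    if reps < 2:
        raise ValueError("reps must be >= 2")
    if rng is None:
        rng = np.random.default_rng()
    baseline = infer_fn(samples)
    n = baseline.n_taxa
    out: dict[float, np.ndarray] = {}
    for eta in eta_grid:
        unchanged = np.zeros((n, n))
        for _ in range(reps):
            noisy = add_noise(samples, float(eta), rng)
            inferred = infer_fn(noisy)
            same = (
                inferred.determined
                & baseline.determined
                & (inferred.values == baseline.values)
            )
            unchanged += same
        out[float(eta)] = 100.0 * unchanged / reps
    return out


def _accuracy_once(
    kind: str,
    n_taxa: int,
    omega: int,
    presence: PresenceModel,
    psi: int,
    rng: np.random.Generator,
    connectivity: float = 0.4,
) -> float:
    """One draw of the simulate-infer-score experiment (overall accuracy %)."""
    from .heuristic import infer_sign_matrix  # one-way import at call time

    model = random_model(kind, n_taxa, connectivity, rng=rng)
    try:
        samples, _ = generate_sample_set(model, omega, presence, rng=rng)
    except RuntimeError:
        return np.nan
    inferred, _ = infer_sign_matrix(
        samples, method="heuristic", psi=psi, seed=int(rng.integers(2**31 - 1))
    )
    truth = jacobian_sign_truth(model)
    return sign_accuracy(inferred, truth).accuracy_overall


def plateau_accuracy_experiment(
    kind: str,
    n_taxa: int = 8,
    n_realizations: int = 10,
    psi_factor: int = 10,
    omega_factors=(3, 4, 5, 6, 7, 8),
    rng: np.random.Generator | None = None,
    connectivity: float = 0.4,
) -> dict:
    """Saturated sign-inference accuracy of the heuristic at large sample size.

    For each community realization, accuracy is evaluated on noiseless samples
    at sample sizes ``omega = k * N`` for the factors given; the plateau value
    is the mean accuracy over the two largest sample sizes (past the point
    where accuracy stops improving).  Returns per-realization plateaus, the
    overall mean, and the full accuracy-vs-omega curves.
    """
    if rng is None:
        rng = np.random.default_rng()
    presence = PresenceModel.uniform(n_taxa)
    psi = psi_factor * n_taxa
    curves, plateaus = [], []
    for _ in range(n_realizations):
        seed = int(rng.integers(2**31 - 1))
        curve = []
        for k in omega_factors:
            sub = np.random.default_rng([seed, k])
            curve.append(
                _accuracy_once(
                    kind, n_taxa, k * n_taxa, presence, psi, sub, connectivity
                )
            )
        curves.append(curve)
        tail = [a for a in curve[-2:] if np.isfinite(a)]
        plateaus.append(float(np.mean(tail)) if tail else np.nan)
    return {
        "plateaus": plateaus,
        "mean_plateau": float(np.nanmean(plateaus)),
        "curves": curves,
        "omega_grid": [k * n_taxa for k in omega_factors],
    }


def min_sample_size_experiment(
    kind: str,
    n_grid,
    presence_kind: str = "uniform",
    accuracy_target: float = 100.0,
    psi_factor: int = 10,
    n_draws: int = 10,
    omega_step: int | None = None,
    omega_cap_factor: int = 12,
    rng: np.random.Generator | None = None,
    connectivity: float = 0.4,
) -> dict:
    """Minimal sample size Omega* for the heuristic to reach a target accuracy.

    For each community size N, Omega is increased in steps (default N/2)
    until the mean overall accuracy over ``n_draws`` independent communities
    reaches ``accuracy_target`` percent; unreachable targets within the
    ``omega_cap_factor * N`` budget are reported censored.  Also returns the
    slope of the least-squares line Omega* ~ N.
    """
    if not 0 < accuracy_target <= 100:
        raise ValueError("accuracy_target must be in (0, 100]")
    if rng is None:
        rng = np.random.default_rng()
    omega_star: dict[int, int | None] = {}
    for n_taxa in n_grid:
        presence = (
            PresenceModel.uniform(n_taxa)
            if presence_kind == "uniform"
            else PresenceModel.heterogeneous(n_taxa)
        )
        psi = psi_factor * n_taxa
        step = omega_step or max(2, n_taxa // 2)
        cap = min(omega_cap_factor * n_taxa, 2**n_taxa - 1)
        found = None
        omega = step
        while omega <= cap:
            accs = [
                _accuracy_once(kind, n_taxa, omega, presence, psi, rng, connectivity)
                for _ in range(n_draws)
            ]
            accs = [a for a in accs if np.isfinite(a)]
            if accs and np.mean(accs) >= accuracy_target:
                found = omega
                break
            omega += step
        omega_star[n_taxa] = found
    ns = [n for n, o in omega_star.items() if o is not None]
    slope = intercept = np.nan
    if len(ns) >= 2:
        slope, intercept = np.polyfit(ns, [omega_star[n] for n in ns], 1)
    return {
        "omega_star": omega_star,
        "slope": float(slope),
        "intercept": float(intercept),
        "censored": [n for n, o in omega_star.items() if o is None],
    }
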