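"""Synthetic community generator.

Produces the validation setting for the inference methods: random directed
interaction networks, steady states of four population-dynamics models
(generalized Lotka-Volterra plus three saturating functional responses)
restricted to random taxon-presence supports, and multiplicative uniform
measurement noise.  All four models share the factored form
``dx_i/dt = x_i * f_i(x)`` and, by construction, a Jacobian of ``f`` whose
off-diagonal signs equal ``sign(a_ij)`` at every positive state — the
property the sign inference relies on.

Functional forms (c, d > 0 are saturation constants):

* GLV:        f_i = r_i + sum_j a_ij x_j
* Holling II: f_i = r_i + sum_j a_ij x_j / (1 + c x_j)
* DB (Beddington-DeAngelis):
              f_i = r_i + sum_j a_ij x_j / (1 + c x_j + d x_i)
* CM (Crowley-Martin):
              f_i = r_i + sum_j a_ij x_j / ((1 + c x_j)(1 + d x_i))
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .samples import SampleSet
from .signs import SignMatrix

__all__ = [
    "EcologicalNetwork",
    "DynamicsModel",
    "PresenceModel",
    "random_network",
    "random_glv_model",
    "random_model",
    "glv_steady_state",
    "integrate_to_steady_state",
    "generate_sample_set",
    "add_noise",
    "jacobian_sign_truth",
]

MODEL_KINDS = ("glv", "holling2", "db", "cm")

#: default saturation constants for the non-GLV functional responses
DEFAULT_C = 0.1
DEFAULT_D = 0.1

#: an equilibrium entry below this is treated as an extinction
FEASIBILITY_TOL = 1e-6

#: steady-state residual tolerance for the ODE route
STEADY_TOL = 1e-9


@dataclass
class EcologicalNetwork:
    """Directed, signed, weighted interaction network (the matrix ``a_ij``)."""

    adjacency: np.ndarray
    connectivity: float

    @property
    def n_taxa(self) -> int:
        return self.adjacency.shape[0]


@dataclass
class PresenceModel:
    """Per-taxon probabilities of being present in a random sample support."""

    kind: str  # "uniform" | "heterogeneous"
    probabilities: np.ndarray

    @classmethod
    def uniform(cls, n_taxa: int, p: float = 0.5) -> "PresenceModel":
        return cls(kind="uniform", probabilities=np.full(n_taxa, p))

    @classmethod
    def heterogeneous(
        cls,
        n_taxa: int,
        p_high: float = 0.9,
        p_low: float = 0.3,
        frac_high: float = 0.25,
    ) -> "PresenceModel":
        """A few taxa present almost always, the rest rarely (two tiers)."""
        probs = np.full(n_taxa, p_low)
        n_high = max(1, int(round(frac_high * n_taxa)))
        probs[:n_high] = p_high
        return cls(kind="heterogeneous", probabilities=probs)

    def draw_support(self, rng: np.random.Generator) -> frozenset[int]:
        while True:
            present = rng.random(len(self.probabilities)) < self.probabilities
            if present.any():
                return frozenset(np.flatnonzero(present))


@dataclass
class DynamicsModel:
    """Population dynamics ``dx_i/dt = x_i f_i(x)`` of one of the four kinds."""

    kind: str
    network: EcologicalNetwork
    growth_rates: np.ndarray
    c: float = DEFAULT_C
    d: float = DEFAULT_D

    def __post_init__(self) -> None:
        if self.kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {self.kind!r}")
        self.growth_rates = np.asarray(self.growth_rates, dtype=float)

    @property
    def n_taxa(self) -> int:
        return self.network.n_taxa

    # -- per-capita growth ------------------------------------------------
    def f(self, x: np.ndarray) -> np.ndarray:
        A, r, c, d = self.network.adjacency, self.growth_rates, self.c, self.d
        x = np.asarray(x, dtype=float)
        if self.kind == "glv":
            return A @ x + r
        if self.kind == "holling2":
            return A @ (x / (1.0 + c * x)) + r
        if self.kind == "db":
            denom = 1.0 + c * x[None, :] + d * x[:, None]  # [i, j]
            return (A * (x[None, :] / denom)).sum(axis=1) + r
        # cm
        g = x / (1.0 + c * x)
        return (A @ g) / (1.0 + d * x) + r

    # -- Jacobian of f ----------------------------------------------------
    def jacobian_f(self, x: np.ndarray) -> np.ndarray:
        """Analytic ``J_ij = d f_i / d x_j`` at state ``x``."""
        A, r, c, d = self.network.adjacency, self.growth_rates, self.c, self.d
        x = np.asarray(x, dtype=float)
        n = self.n_taxa
        if self.kind == "glv":
            return A.copy()
        if self.kind == "holling2":
            return A / (1.0 + c * x[None, :]) ** 2
        if self.kind == "db":
            denom = 1.0 + c * x[None, :] + d * x[:, None]
            J = A * (1.0 + d * x[:, None]) / denom**2  # valid off-diagonal
            # diagonal: own-term derivative plus d-coupling of the j != i terms
            diag = A.diagonal() / (1.0 + (c + d) * x) ** 2
            off = A * x[None, :] / denom**2
            np.fill_diagonal(off, 0.0)
            J[np.diag_indices(n)] = diag - d * off.sum(axis=1)
            return J
        # cm
        g = x / (1.0 + c * x)
        J = A / ((1.0 + c * x[None, :]) ** 2 * (1.0 + d * x[:, None]))
        off = A * g[None, :]
        np.fill_diagonal(off, 0.0)
        diag = (
            A.diagonal()
            * (1.0 - c * d * x**2)
            / ((1.0 + c * x) ** 2 * (1.0 + d * x) ** 2)
        )
        J[np.diag_indices(n)] = diag - d * off.sum(axis=1) / (1.0 + d * x) ** 2
        return J

    def community_jacobian(self, x: np.ndarray) -> np.ndarray:
        """Jacobian of the full right-hand side ``x_i f_i(x)``."""
        x = np.asarray(x, dtype=float)
        J = x[:, None] * self.jacobian_f(x)
        J[np.diag_indices(self.n_taxa)] += self.f(x)
        return J


def random_network(
    n_taxa: int,
    connectivity: float = 0.4,
    rng: np.random.Generator | None = None,
    diag_value: float = -1.0,
    weight_low: float = 0.2,
    weight_high: float = 1.0,
    scale: float | None = None,
) -> EcologicalNetwork:
    """Directed random interaction network.

    Each off-diagonal ``a_ij`` is non-zero independently with probability
    ``connectivity``; magnitudes are uniform on ``[weight_low, weight_high]``
    with random sign, scaled by ``scale`` (default ``1/N``, which keeps random
    equilibria mostly feasible and stable).  Self-interactions are fixed at
    ``diag_value`` (negative: self-limitation).
    """
    if not 0 < connectivity <= 1:
        raise ValueError("connectivity must be in (0, 1]")
    if rng is None:
        rng = np.random.default_rng()
    if scale is None:
        scale = 1.0 / n_taxa
    present = rng.random((n_taxa, n_taxa)) < connectivity
    magnitude = rng.uniform(weight_low, weight_high, size=(n_taxa, n_taxa))
    sign = rng.choice([-1.0, 1.0], size=(n_taxa, n_taxa))
    A = present * magnitude * sign * scale
    np.fill_diagonal(A, diag_value)
    return EcologicalNetwork(adjacency=A, connectivity=connectivity)


def random_growth_rates(
    n_taxa: int,
    rng: np.random.Generator,
    low: float = 0.1,
    high: float = 1.0,
) -> np.ndarray:
    return rng.uniform(low, high, size=n_taxa)


def random_model(
    kind: str,
    n_taxa: int,
    connectivity: float = 0.4,
    rng: np.random.Generator | None = None,
    **network_kwargs,
) -> DynamicsModel:
    """Random network + random positive growth rates, wrapped as a model."""
    if rng is None:
        rng = np.random.default_rng()
    net = random_network(n_taxa, connectivity, rng=rng, **network_kwargs)
    r = random_growth_rates(n_taxa, rng)
    return DynamicsModel(kind=kind, network=net, growth_rates=r)


def random_glv_model(
    n_taxa: int,
    connectivity: float = 0.4,
    rng: np.random.Generator | None = None,
    **network_kwargs,
) -> DynamicsModel:
    return random_model("glv", n_taxa, connectivity, rng=rng, **network_kwargs)


def glv_steady_state(
    model: DynamicsModel, support: frozenset[int] | set[int]
) -> np.ndarray | None:
    """Interior equilibrium of the GLV model on a support, or None.

    Solves ``A_s x_s = -r_s`` on the support; accepted only if strictly
    positive (feasible) and linearly stable (all eigenvalues of the
    support-restricted community Jacobian have negative real part).
    """
    if model.kind != "glv":
        raise ValueError("glv_steady_state requires a GLV model")
    idx = np.array(sorted(support), dtype=int)
    A_s = model.network.adjacency[np.ix_(idx, idx)]
    r_s = model.growth_rates[idx]
    try:
        x_s = np.linalg.solve(A_s, -r_s)
    except np.linalg.LinAlgError:
        return None
    if np.any(x_s <= FEASIBILITY_TOL):
        return None
    J_s = x_s[:, None] * A_s
    if np.any(np.linalg.eigvals(J_s).real >= 0):
        return None
    x = np.zeros(model.n_taxa)
    x[idx] = x_s
    return x


def integrate_to_steady_state(
    model: DynamicsModel,
    support: frozenset[int] | set[int],
    rng: np.random.Generator | None = None,
    tol: float = STEADY_TOL,
    t_max: float = 1e5,
    x0: np.ndarray | None = None,
) -> np.ndarray | None:
    """Integrate the dynamics on a support until it settles, or give up.

    Starts from a random positive state on the support (absent taxa stay at
    exactly zero: the factored form never resurrects them).  Convergence means
    ``max_i |x_i f_i(x)| < tol``; the endpoint must keep every supported taxon
    above the feasibility threshold and be linearly stable.
    """
    if rng is None:
        rng = np.random.default_rng()
    idx = np.array(sorted(support), dtype=int)
    A = model.network.adjacency
    sub_net = EcologicalNetwork(
        adjacency=A[np.ix_(idx, idx)], connectivity=model.network.connectivity
    )
    sub = DynamicsModel(
        kind=model.kind,
        network=sub_net,
        growth_rates=model.growth_rates[idx],
        c=model.c,
        d=model.d,
    )
    if x0 is None:
        y = rng.uniform(0.1, 1.0, size=len(idx))
    else:
        y = np.asarray(x0, dtype=float)[idx]

    def rhs(_t, state):
        state = np.maximum(state, 0.0)
        return state * sub.f(state)

    t_chunk, t_done = 100.0, 0.0
    while t_done < t_max:
        sol = solve_ivp(
            rhs,
            (0.0, t_chunk),
            y,
            method="LSODA",
            rtol=1e-9,
            atol=1e-11,
        )
        if not sol.success:
            return None
        y = np.maximum(sol.y[:, -1], 0.0)
        t_done += t_chunk
        if np.any(y <= FEASIBILITY_TOL):
            return None  # extinction: not a steady state on this support
        if np.max(np.abs(y * sub.f(y))) < tol:
            if np.any(np.linalg.eigvals(sub.community_jacobian(y)).real >= 0):
                return None
            x = np.zeros(model.n_taxa)
            x[idx] = y
            return x
    return None


def steady_state(
    model: DynamicsModel,
    support: frozenset[int] | set[int],
    rng: np.random.Generator | None = None,
) -> np.ndarray | None:
    """Dispatch: exact linear solve for GLV, numerical integration otherwise."""
    if model.kind == "glv":
        return glv_steady_state(model, support)
    return integrate_to_steady_state(model, support, rng=rng)


def generate_sample_set(
    model: DynamicsModel,
    omega: int,
    presence: PresenceModel | None = None,
    rng: np.random.Generator | None = None,
    max_tries: int | None = None,
) -> tuple[SampleSet, dict]:
    """Collect ``omega`` steady-state samples on distinct random supports.

    Supports are drawn from the presence model; duplicates are rejected, as
    are supports without a feasible, stable interior equilibrium.  Returns the
    sample set plus a log of accepted/rejected support counts.
    """
    if omega < 1:
        raise ValueError("omega must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    n = model.n_taxa
    if presence is None:
        presence = PresenceModel.uniform(n)
    if max_tries is None:
        max_tries = max(200 * omega, 1000)
    seen: set[frozenset[int]] = set()
    rows: list[np.ndarray] = []
    log = {"accepted": 0, "duplicate_supports": 0, "infeasible_supports": 0}
    tries = 0
    while len(rows) < omega and tries < max_tries:
        tries += 1
        supp = presence.draw_support(rng)
        if supp in seen:
            log["duplicate_supports"] += 1
            continue
        seen.add(supp)
        x = steady_state(model, supp, rng=rng)
        if x is None:
            log["infeasible_supports"] += 1
            continue
        rows.append(x)
        log["accepted"] += 1
    if len(rows) < omega:
        raise RuntimeError(
            f"could not reach omega={omega} feasible distinct supports within "
            f"{max_tries} draws ({log})"
        )
    samples = SampleSet(abundances=np.array(rows))
    return samples, log


def add_noise(
    samples: SampleSet, eta: float, rng: np.random.Generator | None = None
) -> SampleSet:
    """Multiplicative uniform measurement noise ``x -> x + eta*u, u~U[-x, x]``.

    Applied independently to every non-zero entry; zero entries stay zero and
    for ``eta <= 1`` all entries remain non-negative.
    """
    if eta < 0:
        raise ValueError("eta must be non-negative")
    if rng is None:
        rng = np.random.default_rng()
    x = samples.abundances
    u = rng.uniform(-1.0, 1.0, size=x.shape)
    noisy = np.where(x > 0, x * (1.0 + eta * u), x)
    return SampleSet(
        abundances=noisy,
        taxon_ids=list(samples.taxon_ids),
        sample_ids=list(samples.sample_ids),
        zero_tol=samples.zero_tol,
    )


def jacobian_sign_truth(model: DynamicsModel) -> SignMatrix:
    """Ground-truth interaction-type matrix of a model instance.

    For all four kinds the sign of ``J_ij`` at any positive state equals
    ``sign(a_ij)`` off the diagonal (the saturating responses only rescale
    magnitudes by positive factors), and the self-interaction keeps the sign
    of ``a_ii``.
    """
    return SignMatrix.from_values(np.sign(model.network.adjacency).astype(np.int8))
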