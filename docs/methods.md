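# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `steadynet`, in the order a user meets them: the inference
problem, the two sign-inference algorithms, the quantitative GLV layer, the
simulators used for validation, and the numerical choices that hold it all
together.

## Problem setting and assumptions

The community is assumed to follow autonomous dynamics of the factored form
`dx_i/dt = x_i f_i(x)` on absolute abundances `x ∈ R^N_{≥0}`. The factored
form encodes that absent taxa stay absent, that the all-zero state is a
steady state, and that every observed sample is a non-trivial steady state
(`x_i f_i(x) = 0` for all `i`). The object of inference is the sign-pattern
of the Jacobian `J_ij = ∂f_i/∂x_j`: `+` promotion, `−` inhibition, `0` no
direct interaction.

Two assumptions are made, both checkable:

* **Constant sign-pattern.** `sign(J(x))` does not change across the states
  the samples explore. Violated exactly when the data show *true
  multistability* — two genuinely different steady states on the same taxon
  set — which `detect_true_multistability` tests directly (relative L∞
  difference above 0.05 between same-support samples, after replicate
  averaging). When it fires, the package refuses sign inference: only the
  zero-pattern (topology) is then identifiable.
* **Absolute abundances.** Relative-abundance (compositional) tables make
  every pairwise difference orthogonal to the all-ones vector, so every
  intersection line collapses onto `(1, …, 1)` and the heuristic would
  always propose the all-positive row. `compositionality_guard` detects
  constant row sums (relative tolerance 1e−6) and aborts with an explanatory
  error. This is a hard failure mode of the problem, not of the algorithm.

## Sign-satisfaction

For samples `x^I, x^K` sharing taxon *i*, the mean-value theorem applied to
`f_i(x^I) − f_i(x^K) = 0` yields a vector with sign-pattern `s_i` orthogonal
to `w = x^I − x^K`. Whether a given ternary pattern `s` admits such a vector
is decided in O(N): with products `p_j = s_j w_j`, a compatible vector exists
iff all `p_j` vanish, or products of both signs occur (magnitudes are free,
so mixed signs can always be balanced). The same question phrased as a
linear program — find `v` in the unit box with `v·w = 0` and `sign(v) = s`,
strict inequalities encoded as `|v_j| ≥ ε = 1e−6` — is kept as an
independent oracle; a property test checks the two agree on random
instances. The ε-encoding is exact for inputs whose non-zero coordinates are
well-scaled relative to ε; the LP normalizes `w` to unit max-abs and runs
HiGHS with feasibility tolerances of 1e−10 so that the encoding margin stays
three orders of magnitude above solver noise.

## Brute-force enumeration

All `3^N` patterns are tested against all pairwise differences (vectorized;
a pattern survives iff for every difference row, positive and negative
products are either both present or both absent). The candidate set always
contains the zero pattern and is closed under negation. Enumeration is
refused above `N = 12` (the caller can raise the limit), since the cost is
`3^N · O(pairs · N)`. Notably the brute force needs *more* samples than the
heuristic to become informative: its candidate set only shrinks to the
minimal `{−a, 0, a}` once the differences are diverse enough to kill every
dense pattern, so at moderate sample sizes it returns correct but partially
undetermined rows.

## Intersection-line heuristic

Per taxon row: stack all pairwise differences of the samples containing the
taxon (columns of the difference matrix); repeat Ψ times — draw `N−1`
distinct differences uniformly, compute the null space of the stack by SVD,
accept only a one-dimensional kernel ("the hyperplanes intersect in a
line"; nullity is counted as singular values below 1e−10 × the largest, and
degenerate draws are retried up to 50 times), and score the line's ternary
pattern by φ = fraction of *all* differences it sign-satisfies. With fewer
than `N−1` differences available, all are used and any kernel basis vector
is taken.

Two design points differ from the obvious "take the best line" reading and
were forced by measurement:

* **Per-line zero threshold 0.005.** Line directions are normalized to unit
  max-abs entry; coordinates below 0.5% of the leading entry are read as
  zeros. When the difference hyperplanes are not exactly orthogonal to one
  constant row (saturating dynamics, noise), truly-zero interactions appear
  as small non-zero coordinates (bulk below ~1e−2 at `N = 8`), while the
  weakest real interaction has relative magnitude ~`0.2/N` under the
  default 1/N-scaled weights (0.017 at `N = 12`). 0.005 sits between the
  two for the community sizes the heuristic targets; it is a parameter, and
  communities with much weaker relative interactions need it lowered.
* **φ-weighted consensus instead of the single max-φ line.** A pattern with
  more non-zero entries sign-satisfies hyperplanes more easily, so ranking
  by φ alone is biased toward dense patterns and spurious non-zeros (this
  capped accuracy near 67% on the saturating models). Instead the
  top-quartile lines by φ are orientation-aligned to the best line and each
  entry takes a sign only if one sign holds a strict φ-weighted majority;
  entries whose sign flips across high-confidence lines are zeroed. The
  best φ is still reported as the row's confidence. With this estimator the
  heuristic recovers 100% of signs on noiseless data from all four dynamics
  models at `N = 8` (and GLV at `N = 12`).

Two structural degeneracies of real sample sets are handled explicitly. A
taxon that never varies across the samples sharing the focal taxon
contributes an identically-zero column to the difference matrix, which would
put a spurious basis vector into every null space. If the remaining
coordinates are fully spanned by the differences, the intersection line *is*
that coordinate axis — the isolated-taxon case, where the focal taxon
interacts with nothing and its abundance is constant — and the row resolves
to pure self-regulation. If instead the remaining coordinates leave a
one-dimensional kernel, that reduced kernel is the line and the degenerate
coordinates are reported as *unidentifiable*: when two taxa have no stable
co-existence state (competitive exclusion), no steady-state data can reveal
their interaction, and the corresponding entries are marked undetermined
rather than silently set to zero. These entries are counted as incorrect in
the accuracy experiments, which is why the GLV plateau occasionally measures
slightly below 100% even though every determined sign is correct.

The candidate set `{−a, 0, a}` of the consensus pattern is resolved by prior
knowledge of one non-zero sign; by default the self-interaction is pinned
negative (`s_ii = −`, the usual stability requirement). Entries on which
surviving candidates disagree are reported *undetermined*, never guessed.
Default Ψ = 5N (10N in the validation experiments); all draws flow from one
seeded generator, so results are reproducible bit-for-bit.

## Quantitative GLV layer

Under GLV (`f_i = Σ_j a_ij x_j + r_i`) all samples containing taxon *i*
satisfy `a_i · x + r_i = 0`: they lie on a hyperplane with normal `a_i`.

* **Consistency check.** OLS of `x_i` on the other taxa over those samples;
  R² near 1 means GLV-consistent. Rows below R² = 0.9 (configurable) are
  flagged, and their quantitative estimates should be discarded in favor of
  sign inference. Fits with fewer samples than taxa are reported
  under-determined. Note R² is also degraded by measurement noise, so a low
  value on noisy data is evidence against *usable* GLV structure, not proof
  of non-GLV dynamics.
* **Exact fit.** With one entry pinned (`a_ii`, default −1 — the inference
  is otherwise only determined up to a per-row scale), least squares on the
  homogeneous difference system `a_i · (x^I − x^K) = 0` recovers noiseless
  rows to machine precision; rank deficiency is flagged and yields
  strengths relative to `a_ii` on the identified subspace.
* **Growth rates** are `r_i = mean(−a_i · x^I)` over the samples containing
  the taxon.
* **Lasso.** On noisy data the row is fitted as
  `x_i = Σ_{j≠i} (−a_ij/a_ii) x_j + (−r_i/a_ii)` with `LassoCV` (10-fold,
  100-point logarithmic λ grid). When `a_ii` is unknown it is drawn from the
  half-normal prior `−|N(−1, 0.1²)|`, one draw per row. Cross-validated
  Lasso is accurate in magnitude but liberal in support: under the standard
  validation conditions its FDR plateaus near 0.45.
* **Knockoff filter.** Fixed-X equicorrelated knockoffs (Gram matrix
  preserved, cross-correlations reduced by `s = min(2λ_min, 1)`), the Lasso
  signed-max path statistic, and the knockoff+ threshold at user level `q`;
  selected coefficients are re-fitted by OLS. Designs with
  `p ≤ n < 2p` are handled by the standard row augmentation (zero rows in
  the design, residual-scale Gaussian rows in the response); constant
  columns are excluded from selection; with `n < p` the construction is
  infeasible and the Lasso-only row is returned with a warning. The
  construction identities and the FDR guarantee are unit-tested on
  Gaussian designs. On ecological data the guarantee applies to the working
  linear regression; at high noise (η ≳ 0.25 under the default generator)
  errors-in-variables bias gives truly-zero entries working-model
  coefficients comparable to real ones, and the FDR *measured against the
  generating network* can exceed `q` even though the filter behaves
  correctly for the regression it sees.
* **NRMSE.** Reported as range-normalized RMSE — RMSE over all matrix
  entries divided by `max − min` of the true values, analogously for `r`.
  A Frobenius-relative error over off-diagonal entries was considered and
  rejected: with interaction strengths scaling as 1/N it saturates near 1
  under modest noise and mostly measures the shrinkage of tiny
  coefficients, whereas the range-normalized form stays interpretable
  across community sizes.

## Simulators

The validation setting is generated, not loaded:

* **Networks.** Directed Erdős–Rényi-style: each off-diagonal `a_ij` is
  non-zero independently with probability = connectivity (default 0.4),
  magnitude uniform on `[0.2, 1]` with random sign, scaled by 1/N;
  `a_ii = −1`. The 1/N scale keeps random subsets of taxa overwhelmingly
  feasible and stable, which is what makes large presence-pattern scans
  possible; it also means inter-taxa couplings are weak relative to
  self-limitation, a regime typical of diverse communities. Growth rates
  are uniform on `[0.1, 1]`.
* **Dynamics.** Four kinds sharing `dx_i/dt = x_i f_i(x)`:
  GLV; Holling II `f_i = r_i + Σ_j a_ij x_j/(1 + c x_j)`;
  Beddington–DeAngelis `f_i = r_i + Σ_j a_ij x_j/(1 + c x_j + d x_i)`;
  Crowley–Martin `f_i = r_i + Σ_j a_ij x_j/((1 + c x_j)(1 + d x_i))`, with
  saturation constants `c = d = 0.1`. These are the standard textbook forms
  for the named responses; their off-diagonal Jacobian signs equal
  `sign(a_ij)` at every positive state by construction, and the diagonal
  signs are verified numerically on random states in the tests. Analytic
  Jacobians are implemented for all four and checked against finite
  differences.
* **Steady states.** GLV equilibria are solved linearly on the support
  (`A_s x_s = −r_s`) and accepted only if strictly positive and linearly
  stable (all eigenvalues of `diag(x_s) A_s` in the left half-plane). The
  other kinds are integrated (LSODA, rtol 1e−9 / atol 1e−11, in chunks up
  to t = 1e5) from a random positive state on the support until
  `max |x_i f_i| < 1e−9`, rejecting runs with extinctions or unstable
  endpoints. The two routes agree on GLV to 1e−6 (tested).
* **Presence patterns.** Supports are drawn per taxon: *uniform* —
  probability 0.5 each; *heterogeneous* — two tiers, 25% of taxa at 0.9 and
  75% at 0.3 (a caricature of communities with a few near-ubiquitous taxa).
  Duplicate supports and infeasible supports are rejected and logged.
* **Noise.** Multiplicative uniform measurement noise: each non-zero entry
  `x → x + ηu` with `u ~ U[−x, x]`; zeros untouched; entries stay
  non-negative for η ≤ 1.

What the generator does *not* emulate: sampling depth/compositional
measurement pipelines, demographic stochasticity, migration or invasion
during measurement, environment-dependent interaction rewiring, and
higher-order interactions. Passing tests therefore demonstrate correctness
of the algorithms under the stated model class, not robustness to every
feature of real metagenomic data.

## Validation experiments and problem sizes

The acceptance script and test-suite experiments use: quantitative targets
at `N = 50`, connectivity 0.4, `Ω = 5N = 250` samples, 10 realizations per
noise level, noise grid up to η = 0.25; sign-inference plateaus at `N = 8`,
Ψ = 10N, sample sizes stepped as `Ω = kN, k = 3 … 8`, with the plateau taken
as the mean accuracy over the two largest sample sizes; the minimal sample
size Ω* is scanned in steps of N/2 with 6 community draws per candidate Ω
(target: mean accuracy 100%), on `N ∈ {6, 8, 10, 12}` for the uniform
presence pattern and `N = 8` for the heterogeneous one. Accuracy is the
percentage of correctly inferred signs over the full N×N matrix, with
undetermined entries counted as not correct; the FDR of strength inference
is the fraction of off-diagonal entries inferred non-zero whose true value
is zero, pooled matrix-wide (a per-row alternative exists in the evaluation
code but the matrix-wide pooling is what the headline numbers use).

## Known limitations

* The heuristic's zero threshold couples to the interaction-strength scale;
  very weak true interactions (relative magnitude below ~0.005 of the
  self-interaction) are classified as absent.
* The knockoff FDR guarantee is for the working regression; under strong
  multiplicative noise the measured-against-truth FDR exceeds `q` (see
  above).
* Brute-force enumeration is exponential and capped at `N = 12`; its
  candidate sets at moderate Ω are honest but wide.
* Growth-rate estimates inherit any bias in the fitted rows; no attempt is
  made to de-bias errors-in-variables regression.
* The multistability detector only sees supports that were sampled at least
  twice; sparse surveys can miss true multistability.
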