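# Methods

## Scope

`sfnet` implements a family of clustering coefficients for weighted
multiplex networks — most importantly a *weighted structure-function
clustering coefficient* — together with the in-silico pipeline used to
exercise them: Wilson-Cowan neural-mass dynamics on a structural connectome,
simulated functional connectivity, bifurcation mapping, degree-preserving
null models and sweeps over the basal-input plane.

## Network measures

All layers are undirected, non-negative, zero-diagonal, with weights
normalised to [0, 1].  Writing `W` for a weight matrix, `k_i = sum_j w_ij`
for the node strength and `(·)_ii` for a diagonal entry:

* **Weighted clustering** `c_w(i) = (W^3)_ii / (k_i^2 - (W^2)_ii)`.
  The numerator is the strength of triangles through `i`, the denominator
  the strength of neighbour pairs.  It reduces exactly to the classic
  binary coefficient `t_i / [k_i (k_i - 1) / 2]`-style formula on {0, 1}
  weights.
* **Weighted multiplex clustering** over `M >= 2` layers counts triangles
  whose two wing edges lie in one layer and whose closing edge lies in a
  *different* layer:
  `C_wm(i) = sum_{a != a'} (W^[a] W^[a'] W^[a])_ii /
  [(M - 1) sum_a (k_i^[a]2 - (W^[a]2)_ii)]`.
* **Structure-function clustering** treats layer 1 as anatomical (SC) and
  layer 2 as functional (FC) and asks: of the structural tuples (two
  structural edges meeting at `i`) that are *not* closed by a structural
  edge, what weight fraction is closed by a functional edge?
  `C_wsf(i) = (W1 (W2 o (1 - W1)) W1)_ii /
  [(k_i^2 - (W1^2)_ii)(1 - c_w(i))]`, with `o` the elementwise product.
  High values mean functional coupling between anatomically unconnected
  regions.
* **Weighted Jaccard (Ruzicka) similarity** `J = sum min(a, b) / sum
  max(a, b)`, the standard [0, 1] overlap of two weight matrices.  (The
  per-entry sum-of-ratios variant is exposed behind a flag for audit but is
  unbounded and not used by the pipeline.)

Nodes with a numerically degenerate denominator (`<= 1e-12`: isolated,
degree one, or a fully clustered structural neighbourhood) are assigned 0
and *included* in node averages.  Zero is the conventional choice for
degenerate clustering and keeps averages well-defined; whether such nodes
should instead be excluded is a judgement call, and per-node vectors are
always available for re-aggregation.

Every measure has a brute-force ordered-triple enumeration oracle
(`sfnet.oracles`) used by the test suite and the `cluster --oracle` CLI
flag; the matrix-product implementation computes only the diagonals of the
triple products (`einsum`), never full `N x N x N` work.

## Connectome preparation

Raw anatomical matrices are degree-normalised, `W = D^{-1/2} A D^{-1/2}`
with `D = diag(k_i)`, which bounds weights in [0, 1] and tempers
high-strength hub rows.  Three cortical representations are derived:
fully weighted; *weighted-topological* (all but the strongest fraction —
default 23% — of connections zeroed, weights kept); and binary (survivors
set to 1).  The retained count is `ceil(f * E)` with `E` the number of
nonzero unordered pairs; counting against all `N (N - 1) / 2` pairs instead
is available via `base='all-pairs'`.  Ties at the cut weight are broken in
lexicographic `(i, j)` order and the count is exact, so functional layers
can later be density-matched to within one edge.  Thresholding operates on
the *normalised* matrix (normalise, then threshold, then binarise).

## Neural dynamics

Each region holds excitatory/inhibitory populations `(u_i, v_i)` obeying
the Wilson-Cowan equations with logistic firing rate
`f(x) = 1 / (1 + e^{-x})`:

    du_i/dt = -u_i + f(c1 u_i - c2 v_i + P + eps sum_j b_ij u_j)
    dv_i/dt = -v_i + f(c3 u_i - c4 v_i + Q)

Defaults `c1 = c2 = c3 = 10`, `c4 = -2` give oscillatory rhythms in
biophysical ranges; `P`, `Q` are the swept basal inputs.  The coupling
`eps` is 1 for the two weighted representations and `1 / <k>` for the
binary one, equalising the order of the input across representations.

Integration is Euler-Maruyama, default `T = 2000`, `dt = 0.01`, burn-in
1000, recording every 10th step (sample spacing 0.1 is far below the O(1)
oscillation periods).  White noise acts on `u` only.

**Noise convention.**  `sigma = 0.01` is read as the *diffusion
coefficient* of the SDE: the per-step increment is `sigma sqrt(dt) xi`.
The alternative reading of `sigma` as a variance rate
(`sqrt(sigma dt) xi`, tenfold larger increments at these values) is
available via `noise_convention='intensity'`, but it is not the default
for an empirical reason: at `sigma = 0.01` the larger increments destroy
phase-locking everywhere beyond the bifurcation boundary, flattening the
structure-function clustering landscape and erasing the multistability
contrast the pipeline is built to measure, whereas the diffusion-coefficient
reading preserves the full phenomenology (similarity ridge hugging the
boundary, low-similarity/high-clustering interior, distinct functional
states across realisations).  Initial conditions, when not supplied, are
i.i.d. uniform on (0, 1) per node, drawn from the run's seed before the
noise stream; runs are bitwise reproducible given (seed, inputs).  The
sigmoid argument is clipped at ±500 (indistinguishable from saturation in
double precision).  The inner loop is numba-compiled with a pure-NumPy
fallback.

## Bifurcation analysis

Single node (`eps = 0`): fixed points are parameterised by
`(u*, v*) in (0,1)^2` through the sigmoid inverse, giving closed-form
`P(u*, v*)`, `Q(u*, v*)`.  With slopes `phi_u = u*(1 - u*)`,
`phi_v = v*(1 - v*)` the Jacobian is
`[[-1 + c1 phi_u, -c2 phi_u], [c3 phi_v, -1 - c4 phi_v]]`; the Hopf locus
is trace = 0 with det > 0 and the saddle-node locus det = 0, both linear in
`phi_v` given `phi_u`, so the curves are swept exactly over a `u*` grid
(default 2000 samples; distance-based comparisons should use a denser
parameterisation, ~8000, so curve sampling resolves the target grid).

Network: at each `(P, Q)` cell the `2N`-dimensional drift is root-solved
(scipy `hybr` with the analytic Jacobian, warm-started by continuation
column-by-column; structured uniform restarts plus a damped-Newton polish
recover the occasional stall on sigmoid plateaus, and failed cells are
marked, never interpolated).  The leading eigenvalue of the analytic
Jacobian classifies cells as stable node/focus or destabilised, with
`|Im| > 1e-8` discriminating Hopf-type from saddle-node-type onset.  The
map tracks destabilisation of one steady-state sheet; it makes no claim
about global attractor structure.

## Functional connectivity

FC is the Pearson correlation of the excitatory series (noise enters `u`,
and regional "activity" is read as the excitatory population) restricted to
`t >= burn_in`.  The correlation matrix is thresholded to the density of
the structural layer used in the simulation: diagonal removed, strongest
`ceil(rho N (N-1)/2)` pairs by *signed* correlation retained (absolute
ranking available by flag), ties lexicographic, survivors clipped to
[0, 1]; for the binary representation survivors are set to 1.  Signed
ranking is used because the SC-FC measures require weights in [0, 1] —
anticorrelations have no place in that space and surviving negatives are
clipped and logged.

## Synthetic connectome

The generator emulates the statistical shape of a DTI-derived cortical
matrix at the density of its top-23%-of-connections regime: `N = 78`
regions in two hemisphere-like blocks, within-block pair density 0.35,
between-block 0.10 (overall ~0.23), log-normal weights (mu = 0, sigma = 1),
resampled until connected, deterministic per seed.  It reproduces symmetry,
heavy-tailed weights, modularity and density — it does **not** reproduce
spatial embedding, hub topography, hemispheric homotopy or any real
parcellation, so passing pipeline tests demonstrate the *mechanism*
(criticality-locked similarity, beyond-criticality multistability) on a
realistic network class, not quantitative agreement with empirical
connectomes.

## Null models

Binary: Maslov-Sneppen double-edge swaps, `10 x E` attempts by default,
rejections (self-loop/multi-edge) counted and logged; degree sequence
preserved exactly.  Weighted variant: the support is rewired by the same
swaps and the original edge-weight multiset is redistributed over the new
support by a seeded permutation — preserving exactly the binary degree
sequence and the global weight distribution, the minimal weighted
generalisation of what the binary null preserves.  Node strengths are
deliberately not preserved (documented contract).  The null multiplex
simulates the dynamics *on the randomised structure* and density-matches
FC to it.

## Sweeps and the multistability contrast

The pipeline sweeps `P in [-6, 2]`, `Q in [-12, 0]` (a window that
brackets the closed Hopf branch and saddle-node folds of the default
parameters).  Each cell runs several realisations with fresh initial
conditions and noise; realisation seeds derive from
`SeedSequence(base_seed, (p_index, q_index, r))`, so results are
independent of execution order, cells are cacheable, and resumed sweeps
are bitwise identical.  Reported per cell: mean SC-FC Jaccard, mean
node-averaged `C_wsf`, and their across-realisation relative dispersions.

The two cells contrasted in the multistability analysis are chosen from
the sweep itself: the Jaccard-maximising cell (expected on the stability
boundary) and the `C_wsf`-maximising cell (expected just beyond it).  The
contrast statistic is a one-sided Mann-Whitney test on per-seed relative
deviations of the SC-FC Jaccard.

## Problem sizes and numerical choices

Default study conditions are `N = 78`, `T = 2000`, `dt = 0.01`; sweeps in
the test suite and acceptance script use 10x10 to 12x12 grids with 2-3
realisations per cell and 12-20 realisations at the two contrast cells —
a deliberate desk-scale choice; all sizes are configurable upward.  Other
numerical constants: topological zeros below 1e-15; symmetry/bound
validation at 1e-10; degenerate clustering denominators at 1e-12;
fixed-point residual (infinity norm) 1e-10; eigenvalue classification and
bifurcation-set residuals 1e-8.  Matrix re-symmetrisation `(W + W^T)/2` at
construction keeps downstream algebra exactly symmetric.

## Known limitations

* The weighted null model is one reasonable generalisation of
  Maslov-Sneppen; strength-preserving rewiring is out of scope.
* The stability map classifies one tracked fixed-point sheet; in
  hysteresis bands near folds different continuation paths may track
  different sheets (restarts make this deterministic but not
  sheet-exhaustive).
* Degenerate-node handling (zeros included in means) is a convention, not
  a theorem; per-node outputs allow alternatives.
* FC uses time-averaged Pearson correlation only — no coherence,
  phase-locking or directed measures.
* Edge lists cannot represent trailing isolated nodes (node count is
  inferred from the largest index).
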