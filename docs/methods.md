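# Methods

## Models

**Bidomain tissue model.** Cardiac muscle is treated as two co-located
continua — intracellular and extracellular space — coupled through the
cell membrane. With transmembrane voltage $V$ and intracellular
potential $\Phi_i$ (so $\Phi_e = \Phi_i - V$):

$$
\chi\left(C_m \frac{\partial V}{\partial t} + I_{\text{ion}}(V,\mathbf{g})\right)
  = \nabla\!\cdot\!\hat\sigma_i \nabla \Phi_i - \chi I_{\text{ext}},
\qquad
\nabla\!\cdot\!(\hat\sigma_i + \hat\sigma_e)\nabla\Phi_i
  = \nabla\!\cdot\!\hat\sigma_e \nabla V .
$$

The first equation is parabolic, the second elliptic; the gating/
concentration vector $\mathbf{g}$ obeys pointwise ODEs. $C_m$ and
$\chi$ default to 1 and are folded into the diffusivities. When
$\hat\sigma_e = \nu \hat\sigma_i$, $\Phi_i \propto V$ and the system
reduces to the **monodomain** reaction–diffusion equation with
$\hat D_\text{eff} = \tfrac{\nu}{1+\nu}\hat D_i$ — a reduction the test
suite checks at the discrete level.

**Kinetics library.** Models come in two formats. *rhs* models expose a
derivative function (cubic FitzHugh–Nagumo `fhncub`, Barkley `fhnbkl`,
Nagumo/ZFK `zfk`); models that are not plain ODE systems may provide a
direct time-stepping function instead. *ionic* models partition the
state into non-gate variables, gating variables with rates
$\alpha(V), \beta(V)$, and Markov-chain blocks $\dot u = M u$ whose rate
matrix is declared as a sum of univariate parts plus an optional small
multivariate remainder (Hodgkin–Huxley and configurable synthetic Markov
channels ship in this format). Hodgkin–Huxley uses the modern sign
convention, millivolts, rest near $-65$ mV; the removable singularities
of $\alpha_m, \alpha_n$ are filled by their series limits.

## Numerics

**Explicit solvers.** Forward Euler and classical RK4, per grid node.
Measured orders on the linear test equation are asserted in the suite
(≈1 and ≈4).

**Exponential (Rush–Larsen) solvers.** Gates advance by the exact
solution of their linear relaxation with rates frozen at the step start,
$y' = y_\infty + (y-y_\infty)e^{-(\alpha+\beta)k}$ — unconditionally
stable, exact at clamped voltage, and gate values stay in $[0,1]$.
(The exponential factor must multiply $y_n$ and the equilibrium term be
additive; transposing the two roles would not be exact at constant
voltage.) Markov
blocks advance by the matrix exponential of the frozen rate matrix,
computed by eigen-decomposition with a verification of the
reconstruction ($\|S\Lambda S^{-1}-M\| \le 10^{-8}\|M\|$, imaginary
residue $\le 10^{-10}$) and a scaling-and-squaring fallback for
defective matrices. Multivariate matrices declared as sums of
univariate parts are integrated by Lie splitting over the parts in
declaration order; the remainder goes by forward Euler.

**Tabulation.** Univariate gate coefficients and Markov step matrices
are precomputed at start-up on a uniform grid of the control variable
(default 20 000 nodes over the model's declared range). Lookup is
nearest-node with exact ties to the lower index; out-of-range queries
clamp and are counted. Nearest-node lookup makes the table error
$O(1/n)$; at $n = 10^5$ a full Hodgkin–Huxley action potential deviates
by a few mV·10⁻³ from direct evaluation (asserted, together with the
$1/n$ trend, in the suite).

**Anisotropic diffusion stencil.** The operator
$Lu = \partial_j D_{jk}\partial_k u$ with the transversely isotropic
tensor $D = D_\perp I + (D_\parallel - D_\perp) f f^T$ is discretized on
a 19-point stencil (6 faces, 12 edges, centre; full corners carry zero
weight). Face weights $\psi_{p+q} D_{jj}/h^2$ plus a tensor-gradient
correction $\psi_{p+q}\psi_{p-q}(4h^2)^{-1}\sum_j (D_{jk}^{p+e_j} -
D_{jk}^{p-e_j})$; edge weights $\pm\psi_{p+q}D_{jk}/(2h^2)$; the centre
weight is the negative sum of all others, so constants are in the
kernel at every node. Multiplying every neighbour reference by the
tissue indicator $\psi$ annihilates links into the void; this *is* the
no-flux boundary condition on the staircase boundary — no boundary code
exists. In the gradient correction, a probe $D^{p\pm e_j}$ landing on a
void node drops that $j$-contribution; this keeps the scheme defined at
boundaries without inventing tensor extensions. 2D grids restrict the
offsets to the plane. Weights are built once per run (geometry and
tensors are static).

**Elliptic solver.** The bidomain elliptic equation uses the same
stencil for the summed tensor. With pure no-flux boundaries the
operator is singular (constants); the pin condition
$\Phi_i(\text{pin}) = u_{\text{pin}}$ is enforced as a *gauge*: the
singular system is iterated and the whole field shifted after each
cycle so the pin value is exact. (Fixing the pin node inside the
iteration leaves the constant error mode visible only through a
point-source residual, which multigrid cannot correct; the gauge form
restores textbook rates.) With a subgrid restriction, outside nodes act
as Dirichlet data and the pin, if given, is a fixed node.

Full Multigrid: nested iteration from the coarsest level, then V-cycles
with multicolour Gauss–Seidel (8 colours by coordinate parity — the
19-point stencil couples equal-parity diagonal neighbours, so 2-colour
red-black does not decouple) or Jacobi smoothing; trilinear
vertex-centred prolongation; injection restriction for fields and
full-weighting for residuals, with the weights renormalized over
residual-carrying nodes at boundaries. Coarse levels take every other
node; a coarse node is tissue if any fine node within one step of its
coincident node is (injection-only coarsening loses boundary
connectivity and diverges); coarse operators are rebuilt from the
coarse indicator with the same diffusivities rather than by a Galerkin
product. `delta` is interpreted as the residual-reduction factor
required per nested-iteration level; `vcycles` caps V-cycles per solve,
`maxiter` total smoothing sweeps; convergence is the residual max-norm
against `tolerance`. Divergence (residual 10× above its running
minimum) raises. On full boxes with Dirichlet data the measured
contraction is ≈0.07/cycle; staircase Neumann boundaries of irregular
domains degrade it to ≈0.7/cycle — these grids are small, so the cost
stays negligible, but it is the known limitation of the simple
transfers. Smoother and residual inner loops are jitted (numba) over a
flattened per-node neighbour representation; time-stepped solves warm
start from the previous potential.

## The device ring

One simulation = one ordered list of devices sharing a 4D grid
(3 space dimensions × layers) plus scalar global variables. One ring
turn is one time step: each device runs iff its *when*-flag variable is
nonzero, in declaration order; `t` increments after the last device.
Devices are restricted to a cuboidal subgrid or declared *nowhere*
(globals only; may not write layers). Implemented devices: `k_func`
(assignment programs over a tiny deterministic expression grammar —
arithmetic, comparisons returning exactly 0/1, `mod`, `ifle0`, `abs`,
`min`, `max` — vectorized over nodes with `x, y, z` bound to indices),
`reduce` (max/min/sum/mean over tissue nodes of the subgrid),
`k_poincare` (event detector: first program assignment names the flag
and monitored expression; with sign +1 an event fires when the value
becomes ≥ 0 after being < 0 on the previous turn — crossing-turn
semantics, regression-locked), `k_print`, `record` (`%+.7e`,
x-fastest in space, layer fastest overall), `dump`/`load` (raw
little-endian doubles, layer-slowest then z, y, x-fastest; bit-exact
round trip), `ppmout` (P6, byte = round-half-up of the scaled value
after clamping; z-slices stacked vertically), `singz` (phase
singularities as isoline intersections per 2×2 cell by linear edge
interpolation — exact for linear fields; ambiguous saddle cells are
skipped), `diff`/`diffstep`, `euler`/`rk4`/`rushlarsen`, `elliptic`,
`stop`. Kinetics parameters may be literals, global expressions
(re-evaluated each turn) or `@layer` bindings resolved to per-node
arrays before the call. Geometry-less runs allocate the declared box
and treat the outermost shell as void, which realizes the no-flux
boundary through the indicator exactly as for irregular geometries.
Phase-distribution initial conditions map a one-period recording onto a
per-node phase field with periodic linear interpolation.

Grid-mode `k_func` writes at every node of its restriction, including
void rind nodes; the $\psi$-weighted stencils never read void values,
so this is observationally equivalent to tissue-only writes and keeps
the device vectorizable.

## Verification problems

**Bessel disk (monodomain).** Unit disk, isotropic $D = 1$, no-flux
boundary; initial condition $J_0(\gamma r)$ with $\gamma \approx
3.831706$ the first positive root of $J_0'$ (bracketed on (0, 5) away
from the trivial root, refined by Brent to $10^{-12}$); exact solution
$J_0(\gamma r)e^{-\gamma^2 t}$. Forward Euler with $k = h^2/80$
(rounded so an integer step count lands on $T = 0.2$), error
accumulated **every** step against the cached spatial profile times the
decay factor. Norms: $L^\infty$ = max over time and tissue nodes;
$L^2 = ((T\mu_D)^{-1}\iint \epsilon^2)^{1/2}$ with trapezoid weights in
time and one $h^2$ cell per tissue node ($\mu_D$ = tissue count ×
$h^2$, so a constant error of size $c$ yields both norms $= |c|$).
Four disk-centre offsets relative to the grid — (0,0), (0.2,0.2),
(0.2,0.6), (0.6,0.6) in units of $h$ — average out grid-placement
effects. The default refinement sequence is $h \in \{0.0707, 0.05,
0.0354\}$ ($\sqrt2$ steps): successive-order measurements show the
staircase-boundary error leaves its pre-asymptotic plateau only around
$h \lesssim 0.1$ (on coarser sequences the fitted $L^\infty$ order
drops below 1, which would contradict the scheme's established
behaviour of converging faster than $h^1$ and slower than $h^2$).
Orders are fitted by pooled ordinary least squares of $\log\epsilon$
against $\log h$ over all (h, offset) points.

**Bidomain plane wave.** One-component kinetics
$f(V) = V(V-\alpha)(1-V)$ makes the bidomain system admit exact
travelling fronts $V^* = [1+\exp(\xi/\sqrt{2D^*})]^{-1}$,
$\Phi_i^* = K V^*$, $\xi = x\cos\theta + y\sin\theta - s - ct$, with
$D^{*}_{i,e}$ the directional diffusivities, $D^* = D^*_iD^*_e/(D^*_i +
D^*_e)$, $K = D^*_e/(D^*_i+D^*_e)$ and speed $c = \sqrt{2D^*}(\tfrac12 -
\alpha)$ (verified by substitution; the test suite also measures the
propagating front's speed to within 2% of this value). Parameters:
$L = 10$, $T = 40$, $\alpha = 0.13$, $D_i = (2, 0.2)$, $D_e = (8, 2)$,
$s = -5$, $\theta = 0$ (axis-aligned; configurable), $k = 3h^2/(16
D^e_\parallel)$ for stability. Grid nodes at $x_i = ih$, $i = 0..L/h$;
the outermost ring is the Dirichlet shell, refreshed from the exact
solution at the current time every step; the interior advances by the
splitting sequence diff($D_e$) → elliptic (tolerance $10^{-8}$, warm
started) → diff($D_i$) → Euler kinetics. Errors are measured on $V$
over the interior every step; with $k \propto h^2$ the scheme is
second-order, and the fitted slopes over $h \in \{1, 0.5, 0.25\}$ come
out ≈2.

## Problem sizes and defaults

The disk study runs 3 resolutions × 4 offsets (largest grid ≈ 60²,
12 800 steps); the plane-wave study runs $h \in \{1, 0.5, 0.25\}$
(largest 41² with ≈27 000 steps, each including a multigrid elliptic
solve). `scripts/acceptance.py` reproduces both studies plus the
Bessel root from scratch. All benchmark computations are deterministic;
the script's `--seed` guards auxiliary randomness only.

## Known limitations

* Orthotropic (three-eigenvalue) diffusion tensors are not implemented;
  the tensor field is transversely isotropic by construction.
* Multigrid contraction degrades to ≈0.7/cycle on staircase-bounded
  irregular domains (simple vertex-centred transfers); acceptable at
  desk scale, not at anatomy scale.
* The expression grammar is a deliberately small deterministic subset
  (no user functions, no exponentials); initial conditions needing
  transcendental profiles are set from Python.
* Only the partition *plan* (interval arithmetic, tissue counts, idle
  elimination, load statistics) is computed; there is no message
  passing and no halo exchange.
* `record` output is fixed-width ASCII and `dump` raw doubles; neither
  carries metadata — the configuration that wrote them is the record of
  their layout.
* The synthetic Markov channels are stand-ins for real channel schemes:
  they exercise the decomposition/tabulation/splitting machinery, not
  any specific channel's biophysics.
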