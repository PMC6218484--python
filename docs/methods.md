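# Methods

## Model and assumptions

`logicnet` implements a probabilistic logic ("quantitative Boolean")
network: node activities are real numbers in [0, 1] interpreted as relative
activities of signaling molecules, linked by weighted AND/OR/NOT-style
logic.  A node with activating inputs i and inhibiting inputs j updates as

    x ← clip( Σ_i k_i·g_i · Π_j (1 − h_j·g_j), 0, 1 )

where each gate value g is the source activity (single source), the product
of source activities (AND) or the probabilistic union 1 − Π(1 − x) (OR),
and k, h ∈ [0, 1] are proportionality constants, one per interaction.
Activation is additive-competitive: when a node has two or more activating
interactions, their weights are constrained to sum to exactly 1 (they
compete for the node's activity budget).  Inhibition is multiplicative and
unconstrained in [0, 1].  A single activator's weight is left free in
[0, 1]; fixing it to 1 would make chain weights non-identifiable and the
sum-to-one statement is about *competing* inputs.  This choice is flagged
here because it is a genuine modeling decision, not forced by the
formalism.

The model is fitted to steady-state data: states are iterated
synchronously (all nodes updated from the previous sweep) from a fixed
initial value of 0 for unclamped nodes, inputs and constitutively active
nodes held at their clamp values throughout.  For acyclic networks the
synchronous iteration is exact after (longest-path) sweeps, and the
simulator evaluates exactly that many.  Cyclic networks (the
NFκB–IκBα negative feedback, caspase amplification loops) iterate to a
1e-6 fixed-point tolerance; non-convergence (possible for extreme
parameters during optimization) is reported on the result and the last
state is used, so the optimizer is steered away from oscillatory corners
rather than crashing.  No kinetic/ODE trajectory semantics are implied;
only fixed points are meaningful.

## Objective and optimization

The fitted quantity is the joint parameter set over all contexts
(one value per reaction per context).  The objective is

    MSE + λ1 · Σ √k  (over every parameter instance)
        + λ2 · Σ_g Σ_j |k_j^g − mean(k^g)|  (per-reaction context groups)

MSE is unweighted by measurement SEM (SEMs are carried for plotting and
reporting only).  The L1/2 semi-norm is the sparsity term of choice
because the sum-to-one constraint makes plain L1 constant on competing
activators.  The grouped-L1 term shrinks a reaction's per-context values
toward their mean, collapsing non-different reactions onto a shared value.
Both contexts' data enter one pooled MSE with a single N (joint fitting);
this follows from the single-dataset form of the objective.

Optimization is SLSQP with box bounds [0,1], exact linear equality
constraints (Σk = 1 per competition group per context) and multi-start
(default 10 seeded uniform feasible starts for single fits, 3 inside grid
scans, Dirichlet-sampled within groups).  The non-smooth terms are
smoothed inside the optimizer as √(k + ε) and √((k − k̄)² + ε) with
ε = 1e-8; reported penalty values are exact.  The gradient is analytic:
forward-mode sensitivities of the steady state are accumulated through the
synchronous sweeps (exact for acyclic networks, convergent for cyclic
ones), which is roughly an order of magnitude faster than finite
differences and substantially more reliable near pruned solutions — the
test suite checks it against finite differences to ~1e-8.  Note that
under L1/2 a parameter at exactly 0 is always a local minimum (the
subgradient diverges), so multi-starts, not gradient quality, are what
can move a parameter off 0; regularization-path warm starts therefore
show mild hysteresis by construction.

## Model selection, knockouts, interventions

The (λ1, λ2) grid is half-log-spaced in base 10; the default span
1e-10 … 1e2 gives 25 values plus 0, i.e. 26 per axis and 676 cells.  (A
base-2 reading of the same span would not give 25 values; the base is
configurable.)  Cells are visited in a snake path, each fit warm-started
from its neighbour so parameter estimates move continuously along the
regularization path, plus fresh random restarts to limit path hysteresis.
Each cell is scored by BIC = N ln(MSE) + ln(N) P with P the *effective*
parameter count: reactions below the 0.01 pruning threshold in every
context count 0, reactions whose context values agree within 0.01 count 1,
anything else counts once per context.  The same rule yields the
per-reaction classification {inactive, shared, context_specific}.

In-silico knockout removes a node's incident interactions and forces the
node to 0, keeps the node's measurement rows in the dataset (an essential
measured node then shows up as un-compensatable misfit; dropping the rows
would change N and make AICs incomparable), refits (plain MSE by default —
whether the original screen's knockout refits were regularized is not
documented, so unregularized is the default and configurable), and reports
ΔAIC = AIC_KO − AIC_ref with the reference scaled to 0.  Only the signed
ΔAIC is reported; no biological essentiality labels are hard-coded.  A
knockout that leaves the reduced network with no interactions at all has
no refit and its ΔAIC is undefined (flagged).

Interventions: `knockout` (node to 0, incident edges inert), `clamp`
(node held at a value; outgoing signaling kept), and `remove_incoming`
(the super-repressor idiom: the node's incoming *inhibition* edges —
degradation inputs — are removed while synthesis inputs are kept, so a
non-degradable IκBα keeps being produced but no longer responds to IKK;
a node with no modelled synthesis input falls back to a clamp at its basal
simulated level).  Readouts are reported raw in [0, 1]; an optional linear
calibration to percent apoptosis takes explicit user anchors and is never
applied silently.

## Synthetic data generator

The generator emulates the study design the package targets: two contexts
(a parental/sensitive and a conditioned/resistant cell state), a small set
of stimulation conditions clamping all inputs, 5 replicates per cell,
Gaussian replicate noise with sd = SEM·√replicates truncated at 0 (so the
replicate mean has the requested SEM; the truncation mildly deflates the
SEM of cells near 0), and min-max normalization to [0, 1] per protein
pooled over all contexts, conditions and time points.  Normalize-then-
average is the default (the alternative order is available behind
`average_first`).  Data generated directly on the activity scale are
averaged without rescaling (`average_raw`) — min-max on such data would
amplify replicate noise for proteins that barely vary.

Ground-truth structure: random acyclic single-source networks with ≥1
input, a spanning set of activation edges (every non-input node reachable),
extra edges with a configurable inhibition fraction (default 0.5), ≥60% of
nodes measured, parameters uniform in [0.2, 0.9] with competition groups
renormalized.  Two structural rules keep the recovery problem
well-posed rather than easy:

* zero and context-specific reactions are drawn only from parameters
  outside competition groups (a single-member change inside a group breaks
  the exact sum constraint) whose targets have a path to a measured node;
* any latent node that cannot reach a measured node is observed instead —
  latent nodes are signal relays; a dead-end latent chain would carry
  parameters with exactly zero data sensitivity, and no method could (or
  should) recover them.

Context-specific reactions are resampled per context with pairwise gaps
≥ 0.3.  What passing recovery tests on these data does *not* show: real
immunoblot data have correlated, non-Gaussian errors, unmodelled topology
mismatch, and proteins whose activities are observed only through
proxies; the generator's clean separation of shared/zero/specific classes
is also idealized.

The packaged melanoma network (19 nodes, 29 parameters, 7 measured
proteins: AKT, ERK, FLIP, XIAP, IκBα, NFκB, PARP) is a synthetic
reconstruction: the named inhibitions (FLIP ⊣ cleaved caspase-8,
BCL2 ⊣ cleaved caspase-3, XIAP ⊣ cleaved caspase-3) and the canonical
TRAIL→caspase, TRAIL→TAK1→IKK→NFκB→(FLIP, XIAP, BCL2, IκBα),
BRAF(V600E, constitutive)→MEK→ERK and PI3K→AKT chains are
literature-anchored; the remaining edges complete the printed counts and
are not authoritative.  Its synthetic truth encodes the resistance
phenotype in six context-specific reactions dominated by the XIAP ⊣
caspase-3 edge (0.0135 parental vs 0.8715 conditioned); four reactions
(including the FLIP and BCL2 inhibitions) are 0 in both contexts; 19 are
shared, giving 31 effective parameters against 58 free ones.  A divergence
schedule over the 1–48 h time labels peaks at 4 h, 16 h and 48 h
(initiation/execution/adaption phases).

## Numerical choices and problem sizes

* Simulator tolerance 1e-6, max sweeps 100·|V|, init 0; inhibition factors
  are accumulated in log space with a 1e-300 floor.
* Optimizer: SLSQP, ftol 1e-9, max 200 iterations per start (300 in the
  recovery study); equality constraints satisfied to ~1e-9 and re-imposed
  exactly (group renormalization) on the reported parameter set.
* AIC/BIC with MSE = 0 substitute machine epsilon and warn.
* Reduced scan grids in tests and the acceptance script use 0 plus
  half-log 1e-4 … 3.16e-2 (7 values per axis): the subrange of the full
  grid where the penalty magnitude is commensurate with the noise-floor
  MSE (penalty sums are O(10) per unit λ; the data MSE floor is ~4e-4).
  The recovery study uses 12-node/16-reaction truths, 4 corner
  stimulation conditions, 5 seeds; these sizes keep a full run in the
  low minutes while leaving every qualitative behavior visible at larger
  sizes.
* The recovery study's value-accuracy metric is the RMSE over parameters
  that are truly shared and recovered as active.  Parameters pruned
  despite being truly active are classification errors (scored by the
  label-accuracy metric); some of them have data sensitivity of ~0.003
  at the study noise level and are unresolvable in principle, so
  including their values would measure the identifiability of the random
  draw rather than recovery quality.

## Known limitations

* The gate algebra for multi-activator nodes follows the additive-
  competitive description above; other toolboxes in this family are not
  bit-identical on OR-typed multi-activator nodes, so cross-toolbox
  comparisons should be made at the level of fits, not raw activities.
* No global-optimality guarantees and no Hessian-based identifiability
  analysis; multi-start SLSQP only.
* Knockout ΔAIC compares effective parameter counts of *fitted* models;
  unidentifiable parameters that happen to stay above the pruning
  threshold inflate P by one each in both reference and reduced fits.
* The melanoma fixture's edge set beyond the named interactions is a
  plausible reconstruction, and all packaged measurement tables are
  synthetic; nothing in this repository is measured data.
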