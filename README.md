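# logicnet

Contextualization of probabilistic logic signaling networks: fit one signed
logical network jointly to protein data from several cellular contexts, let
a combined L1/2 + grouped-L1 penalty decide which reactions are inactive,
shared, or context-specific, select the model by BIC over a regularization
grid, and interrogate the result with in-silico knockouts and intervention
predictions.

The package is aimed at systems biologists who model steady-state
(phospho-)protein measurements — e.g. normalized immunoblot panels from a
sensitive and a resistant cell line — with quantitative logic models, and
who want a reproducible answer to "which interactions differ between these
two cell states, and which perturbation would revert the phenotype?"

## Model

Nodes carry relative activities x in [0, 1].  Each node updates as

    a = Σ_i k_i · g_i                     (incoming activations)
    x = a · Π_j (1 − h_j · g_j)           (incoming inhibitions)

with gate value g equal to the source activity (single source), the product
of sources (AND), or the probabilistic union 1 − Π(1 − x) (OR).  States are
iterated synchronously to a fixed point; with all parameters 1 the model
reduces to a Boolean network.  Competing activators of one node satisfy
Σ k = 1 exactly.

The joint parameter set K over all contexts minimizes

    (1/N) Σ_i (X_i − X̂_i)²  +  λ1 Σ_k √k  +  λ2 Σ_g Σ_j |k_j^g − mean(k^g)|

where the L1/2 semi-norm prunes reactions (a plain L1 is constant under the
sum-to-one constraint) and the grouped-L1 term collapses a reaction's
per-context values onto a shared mean.  The (λ1, λ2) pair is screened over
a half-log grid (default 1e-10 … 1e2, 26 values per axis, 676 models);
each cell is scored by BIC = N·ln(MSE) + ln(N)·P with P the effective
parameter count (reactions below 0.01 count 0, context-identical reactions
count 1) and the minimum-BIC cell is selected.  Knockouts are scored by
ΔAIC = AIC(KO) − AIC(reference), AIC = N·ln(MSE) + 2P.

## Worked example

```python
import logicnet as ln

net, template = ln.melanoma_fixture()          # 19 nodes, 29 parameters
truth = ln.melanoma_synthetic_truth()          # synthetic two-context set
table = ln.melanoma_synthetic_tables(seed=0, time_labels=["16h"])["16h"]

rep = ln.predict(net, truth, table, [ln.Intervention("knockout", "XIAP")])
print(rep.readout("parental", "IZI", "none"))           # 0.639
print(rep.readout("conditioned", "IZI", "none"))        # 0.361
print(rep.readout("conditioned", "IZI", "knockout(XIAP)"))  # 0.641
```

The three numbers are steady-state apoptosis readouts in [0, 1] under
death-ligand stimulation: the parental (sensitive) context commits to
apoptosis (0.639), the conditioned (resistant) context is protected by a
strong XIAP → caspase-3 inhibition (0.361), and knocking XIAP out restores
the parental response (0.641) — a full in-silico re-sensitization.

The `examples/` directory holds one short script per capability
(simulation, joint fitting, BIC grid scan, knockout analysis, intervention
prediction, context-difference profiling); each prints its numbers with a
line on what they mean.  A thin CLI (`logicnet simulate|fit|scan|knockout|
predict|generate|normalize`) wraps the same functions and writes a JSON
manifest per run.

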