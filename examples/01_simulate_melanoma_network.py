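"""Steady-state simulation of the packaged melanoma signaling network.

Loads the 19-node TRAIL-agonist network, applies the synthetic two-context
parameter set, and prints the steady-state activity of every node with and
without death-ligand stimulation.  Activities are relative (0 = inactive,
1 = fully active); the parental context responds to stimulation with
strong caspase/PARP activation while the conditioned (resistant) context
does not.
"""

import logicnet as ln

net, template = ln.melanoma_fixture()
truth = ln.melanoma_synthetic_truth()

print(f"network: {len(net.nodes)} nodes, {len(net.parameters)} parameters, "
      f"{len(net.measured_nodes)} measured proteins\n")

for ctx in truth.contexts:
    for label, clamp in [("untreated", 0.0), ("TRAIL-agonist", 1.0)]:
        state = ln.steady_state(net, truth, {"IZI": clamp}, context=ctx)
        apo = state.activities["Apoptosis"]
        print(f"{ctx:12s} {label:14s} apoptosis={apo:.3f} "
              f"(converged in {state.sweeps_used} sweeps)")
print("\nThe parental context commits to apoptosis under stimulation; the "
      "conditioned context is protected by its strong XIAP-mediated "
      "caspase-3 inhibition.")
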