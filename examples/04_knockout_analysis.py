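"""Systematic in-silico knockouts scored by dAIC.

Fits a per-context reference model on synthetic melanoma-style data at the
most divergent time point, removes each non-input protein in turn, refits,
and reports dAIC = AIC(knockout) - AIC(reference).  Positive dAIC means
the network cannot compensate for the loss (the node is essential for
describing the data); negative dAIC means the reduced model is preferred.
"""

import logicnet as ln

net, _ = ln.melanoma_fixture()
tables = ln.melanoma_synthetic_tables(seed=0, time_labels=["16h"])

report = ln.knockout_scan(
    net, tables, ln.FitSettings(restarts=2, seed=0, max_iter=150)
)

for ctx in ["parental", "conditioned"]:
    sub = report.table[
        (report.table.context == ctx) & (report.table.node != "(reference)")
    ].sort_values("delta_aic", ascending=False)
    top = sub.head(5)
    print(f"\n{ctx}: top knockout effects at 16h (dAIC, + = essential)")
    for row in top.itertuples(index=False):
        print(f"  {row.node:8s} {row.delta_aic:+9.1f}")
print("\nThe constitutive MAPK chain and the receptor are essential in both "
      "contexts; the pro-apoptotic PARP ranks high only in the sensitive "
      "parental context, while the NFkB-driven FLIP enters the top ranks "
      "in the resistant conditioned context.")
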