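"""Refine a miRNA target-prediction prior against target co-expression.

Builds a small synthetic dataset (20 miRNAs x 60 genes, one tissue), runs the
message-passing refinement and prints the convergence trace summary plus the
strongest refined edges.  Edge weights are z-score-like: large positive
values mark regulator-gene pairs supported jointly by the prior and by the
co-expression of the regulator's targets.
"""
import numpy as np

import pumanet as pn

cfg = pn.SimulationConfig(seed=1)
data = pn.simulate(cfg)
prior, expr = data["priorA"], data["expression"][0]

net = pn.run_puma(
    prior, expr, mirna_ids=data["mirna_ids"],
    params=pn.PumaParams(alpha=0.1, max_iter=800),
)
print(f"converged: {net.meta['converged']} after {net.meta['iterations']} iterations "
      f"(final h = {net.meta['final_h']:.2e})")

flat = np.argsort(net.weights, axis=None)[::-1][:5]
print("\nstrongest refined edges (regulator -> gene, weight, planted?):")
for k in flat:
    i, j = np.unravel_index(k, net.weights.shape)
    planted = bool(data["truth"].planted[i, j])
    print(f"  {net.regulators[i]} -> {net.genes[j]}  {net.weights[i, j]:6.2f}  {planted}")

rec = pn.evaluate_recovery(net, data["truth"])
print(f"\nplanted-edge AUROC: {rec['auroc']:.3f} "
      f"(how well refined weights rank planted edges above background)")
print(f"AUROC for planted edges withheld from the prior: {rec['auroc_prior_absent']:.3f} "
      f"(the 'learn new edges' property)")
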