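"""QCC-corrected allelic-imbalance calls on one sample.

Pools two simulated replicate libraries, tests every gene against
balanced expression (AI = 0.5) with Bonferroni correction, and shows
how the number of significant genes shrinks as the assumed
overdispersion (QCC) grows — the reason noise calibration matters.
"""

import aseqcc as aq

params = aq.SimulationParams(n_genes=10_000, inflation=2.0, seed=7)
replicates, truth = aq.simulate_experiment(params)
est = aq.estimate_qcc_pair(replicates[0], replicates[1], aq.QCCConfig(seed=7))
print(f"estimated QCC from the replicate pair: {est.qcc:.3f}\n")

for qcc in (1.0, est.qcc, 3.0):
    res = aq.test_point_ai(replicates, qcc=qcc)
    covered = res.merge(truth, on="gene_id")
    frac = ((covered["true_ai"] >= covered["ci_low"])
            & (covered["true_ai"] <= covered["ci_high"])).mean()
    print(f"QCC = {qcc:4.2f}: {int(res['significant'].sum()):5d} genes called imbalanced, "
          f"95% CI covers the true AI for {frac:.1%} of genes")

print()
print("At QCC = 1 (binomial assumption) the intervals are too narrow for these")
print("overdispersed libraries and the true AI escapes them far more often than 5%.")
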