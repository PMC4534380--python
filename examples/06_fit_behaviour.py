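"""Fitting (s, r) to a behavioural summary, and the K' coherence scaling.

A synthetic condition is generated at known parameters, summarised to
(accuracy, mean RT), and refit with the DRAM sampler (short chain for a
desk-scale run). The second part estimates the scaling constant K' of
the law r^2 = K'/coherence from the packaged per-coherence fits.
"""

from battm import (
    BehaviouralSummary,
    fit_kprime,
    load_coherence_table,
    mcmc_fit,
    simulate_summary,
)

s_true, r_true = 4.0, 2.4
acc, rt, _ = simulate_summary(s_true, r_true, n_sim=1000, seed=99)
print(f"synthetic condition at s={s_true}, r={r_true}: "
      f"accuracy={acc:.3f}, mean RT={rt:.0f} ms")

fit = mcmc_fit(
    BehaviouralSummary("synthetic", accuracy=acc, mean_rt_ms=rt),
    chain_len=400, burn=99, thin=3, n_sim=200, seed=555, init=(8.0, 1.2),
)
print(f"recovered best sample: s={fit.best['s']:.2f}, r={fit.best['r']:.2f} "
      f"(discrepancy {fit.best['discrepancy']:.2f}, "
      f"{fit.n_retained} retained samples, "
      f"acceptance {fit.acceptance_rate:.0%})")
print()

k = fit_kprime(load_coherence_table())
print(f"K' = {k:.1f}  (least squares of r^2 = K'/c over all coherences c > 0)")
print("The start point (s=8, r=1.2) is far from the truth; the sampler")
print("walks to the region that reproduces the observed summary. Note")
print("that accuracy and mean RT only weakly identify (s, r): samples")
print("spread along a trade-off ridge, and short chains can report a")
print("ridge point rather than the generating pair.")
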