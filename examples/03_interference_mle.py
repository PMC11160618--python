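"""Maximum-likelihood interference fits and model comparison.

Fits the gamma model (interference strength nu) and the gamma-escape model
(nu plus a non-interfering fraction p) to simulated crossover data, with
individual-level bootstrap confidence intervals.
"""

import numpy as np

from gammaxo import bootstrap_ci, compare_models, fit_gamma, fit_gamma_escape
from gammaxo.likelihood import ChromosomeXO
from gammaxo.simulate import default_chromosome_lengths, simulate_chromosome

rng = np.random.default_rng(3)
lengths = default_chromosome_lengths()
groups = {}
for name, nu, p in [("strong", 14.0, 0.05), ("weak", 9.0, 0.05)]:
    xos = []
    for i in range(120):
        for j, L in enumerate(lengths):
            pos, _ = simulate_chromosome(L / 100, nu, p, rng)
            xos.append(ChromosomeXO(f"{name}{i}", str(j + 1), L, pos * 100))
    groups[name] = xos

group_gamma, group_escape = [], []
for name, xos in groups.items():
    gf = fit_gamma(xos)
    ef = fit_gamma_escape(xos)
    boot = bootstrap_ci(xos, fit_gamma, n_boot=200, seed=4)
    print(f"{name:7s} gamma nu = {gf.nu_hat:5.2f} "
          f"(95% CI {boot.ci95[0]:.2f}-{boot.ci95[1]:.2f});  "
          f"escape nu = {ef.nu_hat:5.2f}, p = {ef.p_hat:.3f}")
    group_gamma.append(gf)
    group_escape.append(ef)

pooled = [c for xos in groups.values() for c in xos]
mc = compare_models(fit_gamma(pooled), fit_gamma_escape(pooled),
                    group_gamma, group_escape)
tab, pw = mc.to_frames()
print("\nmodel table (df, log-likelihood, AIC):")
print(tab.round(1).to_string(index=False))
print("\nnested likelihood-ratio tests:")
print(pw.round(4).to_string(index=False))
# A small p-value for null->full says interference strength differs
# between the groups; gamma->escape says a non-interfering pathway
# improves the fit.
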