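"""Recover planted coverage biases from synthetic fragment-site counts.

Site counts are drawn from the negative-binomial coverage model with a
planted GC spline, flanking-bias table and dispersion (alpha, beta); the
three-step fit should recover all of them.
"""

import numpy as np

from readsmith.covmodel import best_represented_bins, fit_gc_flank
from readsmith.fixtures import TruthProfile, make_genome, simulate_site_counts

genome = make_genome(1, [100_000], gc=0.5)
truth = TruthProfile.smooth(3, alpha=0.5, beta=0.1, norm=4.0)
sites = simulate_site_counts(genome, truth, 150, np.random.default_rng(5))
print(f"{sites.n_sites} fragment sites, mean count {sites.k.mean():.2f}")

fit = fit_gc_flank(sites)
print(f"converged: {fit.converged}")
print(f"alpha: fitted {fit.alpha:.3f} vs planted {truth.alpha}")
print(f"beta : fitted {fit.beta:.3f} vs planted {truth.beta}")

bins = best_represented_bins(fit.sites_per_gc)
truth_gc = truth.gc_bias() / truth.gc_bias()[bins].mean()
mask = fit.sites_per_gc > 100
corr = np.corrcoef(fit.gc_bias[mask], truth_gc[mask])[0, 1]
rmse = np.sqrt(np.mean((fit.flank.table - truth.flank.table) ** 2))
print(f"GC-curve correlation with truth: {corr:.4f}")
print(f"flanking-parameter RMSE: {rmse:.4f}")
# correlation near 1 and RMSE near 0 mean the 128-parameter fit separated
# the GC, flanking and duplication effects correctly
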