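"""Is the Gaussian likelihood trustworthy at your seeding density?

The live-cell likelihood approximates the exact (intractable) birth-death
path law with a multivariate normal. This example measures the empirical
energy distance between simulated count vectors and matched Gaussian draws
at increasing initial cell counts: the distance shrinking toward zero means
the approximation is safe at screening-scale seedings (hundreds to
thousands of cells per well).
"""

import numpy as np

import bdmix as bm

hp = bm.HillParams(b=0.85, E=1.0, m=3.0)   # inert: no drug in this check
model = bm.MixtureModel(
    subpops=[bm.Subpopulation(p=0.4629, beta=0.9058, nu=0.8101, hill=hp),
             bm.Subpopulation(p=0.5371, beta=0.2785, nu=0.2300, hill=hp)],
    n=1000, c=0.0)

scan = bm.gaussian_approx_scan(model, n_list=[10, 100, 1000], reps=4000,
                               n_datasets=3, rng=0)
print(scan.table.to_string(index=False))
print("\nmedian energy distance by initial count:")
print(scan.medians().to_string())
print("\nA monotone decrease with n is the convergence predicted by the "
      "central limit theorem; by n ~ 1000 cells per well the simulated "
      "screen is statistically indistinguishable from its Gaussian limit.")
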