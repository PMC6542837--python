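"""F-gated two-sample comparison of wettability indexes.

Compares mean squeezed diameters of two simulated dish groups with the
variance-gated procedure: an F-test decides between Student's pooled t-test
and Welch's t-test.
"""

import numpy as np

from biofilmwet import gated_t_test

rng = np.random.default_rng(5)
ps_initial = 17.0 + rng.normal(0, 0.4, size=3)  # N = 3 dishes
ps_14d = 6.0 + rng.normal(0, 0.4, size=9)       # N = 9 dishes

res = gated_t_test(ps_initial, ps_14d)
print(f"F = {res.f_statistic:.3f} (p = {res.f_p_value:.3f}) -> {res.test_used} t-test")
print(f"t = {res.t_statistic:.3f}, p = {res.t_p_value:.3g} {res.significance_tier}")
print(
    "\nThe F-test found no variance difference, so the pooled Student t-test"
    "\nwas used; the diameter drop after incubation is highly significant."
)
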