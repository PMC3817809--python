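"""How source recovery degrades with noise, and what spatial filtering buys.

Runs a miniature noise sweep (2 replicates per level) on the artificial
benchmark, with and without a width-7 Gaussian spatial filter.
"""

import conefit as cf

sweep = cf.noise_sweep(
    cf.SyntheticSpec(),
    sigmas=[0.3, 1.0, 2.0],
    filter_width=7,
    k=20,
    c=20,
    reps=2,
    seed=7,
)
print(cf.summarise_sweep(sweep).to_string(index=False))
# At moderate noise the unfiltered pipeline recovers sources nearly
# perfectly; at sigma = 2 recovery collapses without smoothing because too
# few pixels stay similar to the selected source signals, and the Gaussian
# filter restores it by averaging noise down before the decomposition.
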