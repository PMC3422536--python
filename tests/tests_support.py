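"""Shared test settings.

Small, fixed search settings for the stage-1 fit: large enough to recover
the generating parameters within the documented tolerances, small enough
to keep the suite fast.
"""

FIT_KW = dict(n_sim=30, seed=123, maxfev=80,
              sigma_grid=[6.0, 9.0, 12.0], ref_grid=[30.0, 36.0, 42.0])
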