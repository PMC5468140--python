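"""End-to-end pipeline: simulate, fit the four analysis subsets, and print
the aligned coefficient table.

The four subsets mirror the analysis structure: all data combined, the
regional squares only, and the two local wind-farm mountains separately.
"""

import warnings

from pellethglm.report import run_pipeline

config = {
    "seed": 0,
    "design": {"local_half_extent": 800.0, "n_squares": 10,
               "region_radius": 8000.0},
    "model": {"select": False},  # fit the full model in every subset
}

with warnings.catch_warnings():
    warnings.simplefilter("ignore", RuntimeWarning)
    fits, table = run_pipeline(config, out_dir="pipeline_out")

print(table.to_string())
print("\nColumns are analysis subsets; rows are coefficients significant in "
      "at least one subset (stars mark 5% significance, '0.00 (-)' marks a "
      "reference category).  The footer rows give the mean-model dispersion "
      "phi, the CAR dispersion tau and dependence rho, and the number of "
      "plot-year observations used.  All artifacts are under pipeline_out/.")
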