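"""How does internal prediction error scale with the number of injections?

For a random subset of m injected targets, each member is left out in turn
and its out-links within the subset predicted from the other m - 1 rows.
Averaging over subsets gives the internal error as a function of m — how
quickly the predictors learn the network's structure as data accumulates.
"""

import warnings

import tracelink as tl

warnings.filterwarnings("ignore")

ds = tl.macaque_like_dataset(seed=0)
table = tl.internal_error_scaling(
    ds,
    m_values=[5, 10, 20, 29],
    n_rep=8,  # the full analysis uses hundreds of subset draws
    predictor=tl.PredictorConfig("KNN", "regressor", seed=0),
    seed=0,
)
print(table[["weak", "medium_strong", "strong", "all_links"]].round(3).to_string())
# Medium-and-strong-link errors flatten after modest m: the predictors learn
# the rule-based structure quickly, while weak links keep improving slowly.
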