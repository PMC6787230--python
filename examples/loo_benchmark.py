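"""Leave-one-out benchmark: weighted multi-template selection vs random.

Runs the LOO protocol over a 20-entry synthetic complex database at two
identity caps, then compares the weighted multi-template method against
the random baseline with the Wilcoxon signed-rank test.  Expect the
weighted method to have the lower median RMSD, and the loose 80% cap to
be no better than the tight 99.9% cap.
"""

from tcrpmhc import (
    FixtureSpec,
    Method,
    compare_methods,
    loo_run,
    make_template_universe,
    summarize,
)

spec = FixtureSpec(seed=4)
_, _, db, _ = make_template_universe(spec)

records = loo_run(
    db,
    thresholds=(0.999, 0.80),
    methods=(Method.MULTI_WEIGHTED, Method.RANDOM),
    seed=1,
)
table = summarize(records)
print(
    table[
        ["method", "threshold", "n", "tcr_pmhc_rmsd_median"]
    ].to_string(index=False)
)

result = compare_methods(records, Method.MULTI_WEIGHTED, Method.RANDOM)
print(
    f"\nMultiWeighted median {result.median_a:.2f} Å vs "
    f"Random {result.median_b:.2f} Å over {result.n_pairs} paired targets; "
    f"Wilcoxon signed-rank p = {result.p_value:.2e}"
)
print(
    "\nEach row is the median complex Cα RMSD of models built with the\n"
    "target held out of the template pool and candidates capped at the\n"
    "given identity; lower is better."
)
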