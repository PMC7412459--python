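"""Choose the hidden-layer width by repeated cross-validation.

On data generated from the 3-node published model, repeated 9:1 validation
of widths 1..6 should bottom out at 3 — wider nets only add variance.  A
reduced problem (n = 300, 8 repeats) keeps this demonstration quick.
"""

from cmqleaf import (
    FitConfig,
    GeneratorConfig,
    generate_leaf_samples,
    kfold_hidden_node_selection,
    samples_from_frame,
)

samples = samples_from_frame(generate_leaf_samples(GeneratorConfig(n=300, seed=0)))
result = kfold_hidden_node_selection(
    samples,
    k=10,
    repeats=8,
    node_range=range(1, 7),
    config=FitConfig(restarts=3, seed=0),
)

for count, mean, se in zip(
    result.node_counts, result.mean_validation_nll, result.se_validation_nll
):
    print(f"hidden nodes {count}: mean validation NLL {mean:7.1f} (se {se:.1f})")
print(f"selected width (one-SE rule): {result.selected_count}")
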