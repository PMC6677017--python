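"""Per-feature diagnostics: separation, single-feature classifiers, dF1.

For each of the 21 features this prints its correlation with resolution,
the S/N separation between the sulfate and water populations, the accuracy
and F1 of a one-feature logistic classifier, and dF1 — how much the final
classification F1 drops when the feature's values are swapped between the
sulfate and water populations (rank-matched, so the marginals survive).
Redundant features lose little when swapped; features carrying unique
signal lose the most.
"""

from solventscope import evaluate_features, sample_features, train

df = sample_features(40_000, seed=1)
model = train(df, seed=1)

table = evaluate_features(df, trained=model)
table = table.sort_values("snr", ascending=False)
print(table.to_string(index=False,
                      float_format=lambda v: f"{v:+.3f}"))
# expect the volume features (ED3/ED4) and the tetrahedral-probe RSCCs
# (CC4, CC14) at the top, and the rotational spreads (ED1/ED2) near zero
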