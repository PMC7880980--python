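"""Scaled vs unscaled singular vectors: related but different SemD.

Classical LSA scales the left singular vectors by the singular values
(rows of U·Σ); some published diversity norms appear to have used the
unscaled rows of U instead. Both variants are derived from one SVD here
and their SemD tables correlated. Takes ~10 s.
"""

import semdiv

spec, pipe = semdiv.reference_spec()
docs, _ = semdiv.generate_corpus(spec)
cfg = semdiv.RunConfig(window=pipe["window"], min_count=pipe["min_count"],
                       min_contexts=pipe["min_contexts"], k=pipe["k"],
                       scaled=True, seed=spec.seed)
result = semdiv.build_space_from_documents(docs, cfg)

t_scaled = semdiv.semdiv_table(result.space)
t_unscaled = semdiv.semdiv_table(result.space.variant(scaled=False))
report = semdiv.compare_variants(t_scaled, t_unscaled)

print(f"words compared: {report['n']}")
print(f"Pearson r     : {report['pearson_r']:.3f}")
print(f"Spearman rho  : {report['spearman_rho']:.3f}")
print("\nPositive but well below 1: the scaling convention changes the")
print("metric, which is why it matters to record which variant built a norm.")
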