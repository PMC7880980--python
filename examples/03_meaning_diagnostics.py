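"""What do context vectors capture? Topic structure, not word meaning.

Two ambiguous probe words are planted in the reference corpus:

* ``ambisep`` — its two "meanings" live in different topics, so its
  context vectors should separate by meaning (high CH score);
* ``ambinull`` — its two "meanings" are assigned at random with identical
  topic profiles, so nothing geometric distinguishes them (CH ≈ the
  random-label baseline of 1).

The corpus-level diagnostic shows the flip side: contexts cluster
strongly by topic metadata. Takes ~15 s.
"""

import semdiv

spec, pipe = semdiv.reference_spec()
docs, gt = semdiv.generate_corpus(spec)
cfg = semdiv.RunConfig(window=pipe["window"], min_count=pipe["min_count"],
                       min_contexts=pipe["min_contexts"], k=pipe["k"],
                       scaled=pipe["scaled"], seed=spec.seed)
result = semdiv.build_space_from_documents(docs, cfg)
table = semdiv.semdiv_table(result.space)
report = semdiv.ground_truth_report(gt, result.chunks, result.space, table,
                                    seed=0, n_iterations=200)

for word, d in report["ambiguous"].items():
    verdict = "separable" if d.exceeds_baseline else "NOT separable (at baseline)"
    print(f"{word:9s}  CH = {d.ch_score:7.2f}   random-label baseline = "
          f"{d.baseline_mean:.2f} ± {d.baseline_sd:.2f}   -> {verdict}")

domain = semdiv.corpus_label_diagnostic(result.space, "domain", seed=0, n_iterations=200)
print(f"\nwhole corpus by topic label: CH = {domain.ch_score:.1f} "
      f"(baseline {domain.baseline_mean:.2f} ± {domain.baseline_sd:.2f})")
print("Context vectors encode which kind of text a context is, so only")
print("meaning differences that align with topics are visible to them.")
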