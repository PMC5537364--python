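"""Phenotype cases from text features with bootstrap out-of-bag evaluation.

Per bootstrap run, feature discovery, filtering, UPGMA decorrelation and
minimum-p representative selection happen on the resampled cases only;
a Bernoulli naive Bayes classifier is trained on those features and scored
on the out-of-bag cases.  The mean out-of-bag AUC estimates how well the
outcome can be phenotyped from text alone.
"""

from patwas.classify import PipelineConfig, bootstrap_evaluate
from patwas.synth import PlantedPattern, SyntheticSpec, generate

spec = SyntheticSpec(
    n_cases=80, seed=11, sentences_per_doc=3, vocab_size=40,
    planted_binary=(PlantedPattern(("hrhpv", "detected"), p1=0.9, p0=0.05),))
corpus, _ = generate(spec)

report = bootstrap_evaluate(corpus, corpus.outcomes["status"],
                            PipelineConfig(alpha=0.0025), classifier="nb",
                            n_runs=25, seed=11)
print(f"mean out-of-bag AUC over {report.n_runs} bootstrap runs: "
      f"{report.mean_auc:.3f}")
print("first five per-run AUCs:", [round(a, 3) for a in report.aucs[:5]])
print("\nAUC near 1.0 means the planted phrase supports near-perfect "
      "phenotyping; with permuted labels the same pipeline sits near 0.5.")
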