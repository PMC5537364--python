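"""Discover outcome-associated text patterns in a synthetic clinical corpus.

Builds an 80-case corpus in which the phrase "hrhpv detected" is planted in
80% of class-1 cases but only 10% of class-0 cases, runs the full discovery
pipeline, and prints the ranked results.  The top rows should be the planted
phrase (huge odds ratio, tiny Fisher p) and fragments overlapping it.
"""

from patwas.pipeline import RunConfig, discover
from patwas.synth import PlantedPattern, SyntheticSpec, generate

spec = SyntheticSpec(
    n_cases=80, sentences_per_doc=3, vocab_size=40, seed=42,
    planted_binary=(PlantedPattern(("hrhpv", "detected"), p1=0.8, p0=0.1),))
corpus, truth = generate(spec)
planted = truth["binary"][0]
print(f"planted 'hrhpv detected' in {planted['n1']} class-1 and "
      f"{planted['n0']} class-0 cases (realised log OR {planted['log_or']:.2f})\n")

report = discover(corpus, "status", RunConfig(alpha=0.0025))
print(f"{'pattern':<30} {'type':<8} {'stat':<5} {'estimate':>9} {'p':>10} {'support':>8}")
for r in report.results[:8]:
    print(f"{r.rendered():<30} {r.pattern_type:<8} {r.stat:<5} "
          f"{r.estimate:>9.3g} {r.p_value:>10.3g} {r.support:>8}")
print("\nLower p = stronger association; the odds ratio compares pattern "
      "presence between the two outcome classes.")
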