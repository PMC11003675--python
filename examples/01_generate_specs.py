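"""Sample network specifications from the stochastic generator.

The generator draws a hidden-layer chain from a Markov chain over layer
kinds (conv -> pool with probability 0.7, etc.) and each hyperparameter from
a clipped, rounded normal prior, then wraps it in the fixed scaffold
(input / merge / loss_weight / output).  Every emitted spec parses and
builds.
"""

import numpy as np

from serann import GeneratorConfig, build_network, generate_corpus

cfg = GeneratorConfig()
specs = generate_corpus(5, cfg, rng=0)

for text in specs:
    report = build_network(text, cfg.build)
    print(text)
    print(f"  -> valid={report.valid}, trainable parameters = "
          f"{report.parameter_count:,}")

lengths = [len(s.split()) for s in generate_corpus(500, cfg, rng=1)]
print(f"\n500 specs: content length min={min(lengths)} max={max(lengths)} "
      f"(budget 350 tokens)")
print("Each line above is one heritable phenotype; the parameter count is "
      "what the 2,000,000-parameter cap is checked against.")
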