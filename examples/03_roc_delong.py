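"""Score-based ROC/AUC with DeLong confidence intervals per tool.

AUC is threshold-free: it is the probability that a random pathogenic
variant outranks a random benign one on the tool's continuous score
(after orienting scores so that high means damaging — SIFT and PROVEAN
natively run the other way).
"""

import consilico as c

panel = c.generate_panel(c.lqts_benchmark_config(seed=20240))
scores = panel.scores_frame()
truths = panel.truths()

print(f"{'tool':12s} {'AUC':>6s}  95% CI          direction")
for tool in panel.tools:
    res = c.analyze_scores(scores[tool].to_numpy(), truths,
                           direction=panel.polarity(tool))
    print(f"{tool:12s} {res.auc:0.3f}  ({res.ci_low:0.3f}-{res.ci_high:0.3f})"
          f"  {res.direction}")
# AUC 0.5 would be chance; an interval excluding 0.5 means the tool's
# scores carry real ranking signal on this panel.
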