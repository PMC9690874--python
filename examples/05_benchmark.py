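"""All-vs-all quality benchmark of the heuristic against the optimum.

For every pair of a d50-style family both scores are computed.  Reported
per setting (averaged over repeated random sample draws):

* sd — root-mean-square difference between heuristic and optimal score,
  over the pairs where an anchor was used (0 = always optimal);
* utilization — % of pairs where at least one anchor was used;
* exact match — % of utilized pairs aligned with the optimal score.

Longer stored subalignments (larger k) are rarer but safer: utilization
drops while sd shrinks.
"""

from anchalign import (
    FixedScoring,
    LookupConfig,
    evaluate_all_pairs,
    mean_report,
    preset_family,
)

family = preset_family("d50", n_sequences=20, seed=1)
print(f"{'k':>3} {'sd':>8} {'utilization%':>13} {'exact%':>8}")
for k in (5, 10, 15):
    config = LookupConfig(k=k, z=10, scheme=FixedScoring())
    reports = evaluate_all_pairs(family, config, repeats=3, seed=42)
    m = mean_report(reports)
    print(f"{k:>3} {m.sd:>8.3f} {m.utilization_rate:>13.1f} "
          f"{m.exact_match_rate:>8.1f}")
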