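"""Batch-analyse a labelled benchmark collection and compare classes.

Generates a synthetic benchmark (20 planted functional modules + 20
uniform signatures on a 2,000-node scale-free scaffold), analyses every
module, prints the percent-significant summary per class and the
two-tailed KS comparison of the pooled degree distributions.
"""

from mcnet import (
    SynthSpec,
    analyze_collection,
    compare_classes,
    generate_benchmark_collection,
    pool_parameter,
    summarize_collection,
)

bench = generate_benchmark_collection(SynthSpec(seed=8))
results = analyze_collection(bench.modules, bench.scaffold, reps=1000, seed=9)

by_class = {
    cls: [r for r in results if r.attrs.get("class") == cls]
    for cls in ("functional", "signature")
}
print("percent significant (alpha=0.05):")
for cls, rs in by_class.items():
    (s,) = summarize_collection(rs)
    pct = ", ".join(f"{k}={v:.1f}%" for k, v in s.pct_significant.items())
    print(f"  {cls} (n={s.n_analyzed}): {pct}")

cmp = compare_classes(
    pool_parameter(by_class["functional"], "degree"),
    pool_parameter(by_class["signature"], "degree"),
    class_a="functional",
    class_b="signature",
    parameter="degree",
)
print(
    f"pooled degree, functional vs signature: KS p = {cmp.ks_p:.3g},"
    f" direction = {cmp.direction}"
)
# Functional-like modules show network structure (high percent significant,
# pooled degrees stochastically greater); unstructured signatures do not.
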