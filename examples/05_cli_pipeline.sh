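#!/bin/sh
# End-to-end shell pipeline: simulate a benchmark, analyse it, compare
# classes and print a report.  Outputs land under ./scratch/demo.
set -e

OUT=scratch/demo
mcnet simulate --n-nodes 800 --mean-degree 6 --module-size 15 \
    --n-per-class 10 --n-linker 2 --seed 5 --out "$OUT/bench"

mcnet analyze --scaffold "$OUT/bench/scaffold.tsv" \
    --modules "$OUT/bench/modules.gmt" --collection bench \
    --reps 1000 --seed 6 --stratify-by class --out "$OUT/results"

mcnet compare --results "$OUT/results" --out "$OUT/compare" \
    --modules "$OUT/bench/modules.gmt" --dag "$OUT/bench/dag.tsv" \
    --annotations "$OUT/bench/annotations.tsv" --namespaces "$OUT/bench/namespaces.tsv"

mcnet report --results "$OUT/results" --by class
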