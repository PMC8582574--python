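#!/bin/sh
# The same analysis as the Python examples, driven by the CLI: simulate a
# dataset, build the network, enrich hub targets, screen the cohort, and
# consolidate everything into results/report.md. Identical seed + config
# reproduce byte-identical outputs.
set -e
WORKDIR="${1:-pipeline_demo}"

mirnet -v simulate --data-dir "$WORKDIR/data" --out-dir "$WORKDIR/out" --seed 12
mirnet -v network  --data-dir "$WORKDIR/data" --out-dir "$WORKDIR/out" --seed 12
mirnet -v enrich   --data-dir "$WORKDIR/data" --out-dir "$WORKDIR/out" --seed 12
mirnet -v diffexp  --data-dir "$WORKDIR/data" --out-dir "$WORKDIR/out" --seed 12
mirnet -v survive  --data-dir "$WORKDIR/data" --out-dir "$WORKDIR/out" --seed 12
mirnet -v report   --data-dir "$WORKDIR/data" --out-dir "$WORKDIR/out" --seed 12

echo "---- $WORKDIR/out/report.md ----"
cat "$WORKDIR/out/report.md"
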