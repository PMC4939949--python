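#!/bin/sh
# The full command-line workflow on a simulated dataset:
# simulate -> build-index -> search -> evaluate -> abundance.
#
# Run:  sh examples/04_command_line_workflow.sh
set -e
DIR=$(mktemp -d)
trap 'rm -rf "$DIR"' EXIT

prosaa simulate --out-dir "$DIR/data" --families 2 --model-len 120 \
    --homologs 2 --decoys 50 --coverage 10 --seed 1

prosaa build-index "$DIR/data/reads.faa" --out "$DIR/reads.idx"

prosaa search "$DIR/data/families.hmm" "$DIR/data/reads.faa" \
    --index "$DIR/reads.idx" --out-prefix "$DIR/run" --seed 1

prosaa evaluate "$DIR/run.assignments.tsv" "$DIR/data/truth.tsv" \
    --out "$DIR/eval.tsv"

grep -c '^>' "$DIR/run.contigs.faa" | xargs echo "verified contigs:"
echo "--- evaluation ---"
cat "$DIR/eval.tsv"

echo "FAM00	120
FAM01	120" > "$DIR/lens.tsv"
prosaa abundance "$DIR/run.assignments.tsv" --out "$DIR/abundance.tsv" \
    --model-lengths "$DIR/lens.tsv" \
    --total-reads "$(grep -c '^>' "$DIR/data/reads.faa")"
echo "--- abundance ---"
cat "$DIR/abundance.tsv"
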