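#!/usr/bin/env bash
# End-to-end shell pipeline: simulate a reporter locus and reads, then
# quantify repair outcomes at the predicted junction.
set -euo pipefail

OUT=${1:-/tmp/cutfuse_demo}

cutfuse simulate --kind two_cut_locus --scale 3000 --seed 7 \
    --event inversion --n-reads 5000 --read-length 150 \
    --error-rate 0.001 --spectrum "none:0.22,+G:0.56,+GG:0.08,-A:0.12,-AC:0.02" \
    --outdir "$OUT/sim"

cutfuse predict-junctions --config "$OUT/sim/config.yaml" --outdir "$OUT/predict"

cutfuse quantify --config "$OUT/sim/config.yaml" \
    --reads "$OUT/sim/reads.fastq" --outdir "$OUT/quant" --sam

cutfuse explain --config "$OUT/sim/config.yaml" --indel "+T" --kind inversion

echo
echo "spectrum report:"
cat "$OUT/quant/spectrum_inversion_5prime.tsv"
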