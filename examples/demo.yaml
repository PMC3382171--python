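# All-synthetic demo workflow. Generate the inputs first (from this
# directory), then run the pipeline:
#
#   resistkit simulate-plate --ic50 1e-8 --noise-cv 0 --out plate.csv
#   resistkit simulate-combo --model rescue --out combo.csv
#   resistkit simulate-reads --n-pairs 8000 --out-prefix lib
#   resistkit simulate-cnv --noise-sd 0.25 --seed 3 --out probes.tsv
#   resistkit run --config demo.yaml --out report.json
seed: 1
stages:
  - stage: fit_dr
    plate: plate.csv
  - stage: synergy
    matrix: combo.csv
  - stage: detect_fusion
    reads1: lib_1.fq
    reads2: lib_2.fq
    transcripts: lib_ref.fa
  - stage: segment_cnv
    probes: probes.tsv
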