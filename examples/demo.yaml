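# Small end-to-end demonstration run: simulate a 6-session synthetic
# cohort from the winning model, fit three candidate models, compare them
# at the group level, and run the trial-history regressions and
# behavioral metrics.  Execute from the repository root with
#
#   rlstrat run --config examples/demo.yaml
#
seed: 42
out_dir: scratch/demo_run
simulate: true
n_sessions: 6
set_size: 2
presentations_per_odor: 100
generating_model: a0bs1232
models: [a0b-nos, a0bs1, a0bs1232]
n_starts: 10
regression_ids: [1, 2, 3, 4, 5, 6]
run_validation: false
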