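# Reference training recipe (full epoch budget); expect long runtimes
# on desk hardware with large datasets.
seed: 0
region: complete
protocol: kfold_10
k: 10
target_shape: [32, 32, 32]
normalize: zscore
depth: 4
encoder_filters: [8, 16, 32, 64]
upsample_mode: nearest
seg_epochs: 200
clf_filters: [8, 16, 32, 64, 128]
clf_epochs: 200
learning_rate: 0.001
batch_size: 16
l2_lambda: 0.0004
threshold: 0.5
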