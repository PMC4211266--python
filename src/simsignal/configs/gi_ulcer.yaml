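# Upper gastrointestinal ulcer outcome: 45 drugs (23 positive / 22 negative),
# dominated by one large NSAID-like class.
ade_name: upper gastrointestinal ulcer
n_positive: 23
n_negative: 22
n_classes: 25
class_sizes: [12, 6, 3, 2, 2, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1]
n_features: 4192
within_class_jaccard: 0.7
between_class_jaccard: 0.1
n_private_features: 5
label_class_correlation: 0.9
irr_positive: 4.0
exposed_time: 60.0
unexposed_time: 300.0
baseline_rate: 0.02
n_subjects: 1000
seed: 104
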