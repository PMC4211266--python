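# Acute liver failure outcome: 51 drugs (27 positive / 24 negative controls).
ade_name: acute liver failure
n_positive: 27
n_negative: 24
n_classes: 27
class_sizes: [8, 7, 5, 4, 3, 2, 2, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1]
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
seed: 102
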