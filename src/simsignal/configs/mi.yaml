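# Acute myocardial infarction outcome: 47 drugs (24 positive / 23 negative).
ade_name: acute myocardial infarction
n_positive: 24
n_negative: 23
n_classes: 26
class_sizes: [10, 5, 4, 3, 3, 2, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1]
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
seed: 103
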