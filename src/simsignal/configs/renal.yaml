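# Acute renal failure outcome: 49 drugs (25 positive / 24 negative controls)
# with the class-size profile of a mixed reference standard — one large class
# (NSAID-like), several mid-size classes, many singletons — giving 74
# same-class pairs among the 1,176 unordered drug pairs.
ade_name: acute renal failure
n_positive: 25
n_negative: 24
n_classes: 24
class_sizes: [9, 6, 5, 4, 3, 3, 2, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1]
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
seed: 101
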