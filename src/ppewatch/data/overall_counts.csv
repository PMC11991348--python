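split,definition,correct,incorrect
training,no_misclassified_regions,6097,1027
training,no_misclassified_mask_or_gown,6254,870
live,no_misclassified_regions,1624,679
live,no_misclassified_mask_or_gown,1884,419
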