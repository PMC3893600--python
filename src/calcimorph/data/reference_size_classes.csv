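group,total_objects,small_objects,large_objects,macro_excluded
benign,182,93,65,1
malignant,414,262,96,0
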