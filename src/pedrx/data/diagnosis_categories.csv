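category_label,icd_prefixes
Acute upper respiratory infections,J00;J01;J02;J03;J04;J05;J06
Acute bronchitis,J20
Other diseases of upper respiratory tract,J30;J31;J32;J33;J34;J35;J36;J37;J38;J39
Bronchitis nec,J40
Acute lower respiratory infections,J21;J22
Emphysema and chronic obstructive pulmonary disease,J43;J44
Other respiratory diseases,J
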