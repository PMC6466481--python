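method,coefficient
infogain,63
relief,61
std,52
pearson,49
fisher,46
chi2,40
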