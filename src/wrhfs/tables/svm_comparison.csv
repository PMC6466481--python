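method,n_features,tp,sensitivity,tn,specificity,correct,accuracy,youden
WRHFS,9,329,82.7,317,80.4,645,81.5,0.63
infogain,10,297,74.6,284,72.1,574,72.5,0.47
relief,13,277,69.6,290,73.7,577,72.9,0.43
std,20,283,71.1,291,73.9,580,73.2,0.45
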