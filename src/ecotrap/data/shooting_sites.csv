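site,a,b,d_eff
Mary River,49.643,1.338,0.339
Macquarie Marshes,55.552,2.008,1.986
Paroo River,76.282,5.023,2.115
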