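subpop	n_roi	n_genes
cutting	60	134
halter	47	90
racing	77	171
reining	52	81
western_pleasure	39	81
working_cow	57	78
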