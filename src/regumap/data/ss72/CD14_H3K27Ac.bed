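chrS	21389	21409
chrS	22389	22409
chrS	61389	61409
chrS	62389	62409
chrS	101389	101409
chrS	102389	102409
chrS	141389	141409
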