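chrS	4989	5009
chrS	5989	6009
chrS	214989	215009
chrS	215989	216009
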