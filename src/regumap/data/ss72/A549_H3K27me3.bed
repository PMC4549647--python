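chrS	6989	7009
chrS	216989	217009
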