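chrS	184989	185009
chrS	185989	186009
chrS	186989	187009
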