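chrS	187989	188009
chrS	188989	189009
chrS	189989	190009
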