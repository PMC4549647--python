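chrS	59992	60012
chrS	99990	100010
chrS	200989	201009
chrS	201989	202009
chrS	202989	203009
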