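chrS	194989	195009
chrS	195989	196009
chrS	196989	197009
chrS	197989	198009
chrS	198989	199009
chrS	199989	200009
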