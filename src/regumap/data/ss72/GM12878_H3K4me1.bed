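chrS	203989	204009
chrS	204989	205009
chrS	205989	206009
chrS	206989	207009
chrS	207989	208009
chrS	208989	209009
chrS	209989	210009
chrS	210989	211009
chrS	211989	212009
chrS	212989	213009
chrS	213989	214009
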