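chrS	19989	20009
chrS	180989	181009
chrS	181989	182009
chrS	182989	183009
chrS	183989	184009
chrS	184989	185009
chrS	185989	186009
chrS	186989	187009
chrS	187989	188009
chrS	188989	189009
chrS	189989	190009
chrS	190989	191009
chrS	200989	201009
chrS	203989	204009
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
chrS	214989	215009
chrS	215989	216009
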