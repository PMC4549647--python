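chrS	17989	18009
chrS	18989	19009
chrS	57989	58009
chrS	58989	59009
chrS	97989	98009
chrS	98989	99009
chrS	137989	138009
chrS	138989	139009
chrS	177989	178009
chrS	178989	179009
chrS	180989	181009
chrS	181989	182009
chrS	182989	183009
chrS	183989	184009
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
chrS	257989	258009
chrS	258989	259009
chrS	259999	260019
chrS	260039	260059
chrS	260739	260759
chrS	299989	300009
chrS	309989	310009
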