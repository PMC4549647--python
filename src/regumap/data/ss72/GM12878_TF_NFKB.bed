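chrS	19989	20009
chrS	180989	181009
chrS	181989	182009
chrS	182989	183009
chrS	183989	184009
chrS	203989	204009
chrS	204989	205009
chrS	205989	206009
chrS	319989	320009
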