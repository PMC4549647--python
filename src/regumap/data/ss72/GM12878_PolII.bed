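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
chrS	191989	192009
chrS	192989	193009
chrS	193989	194009
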