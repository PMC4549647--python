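chrS	17989	18009
chrS	18989	19009
chrS	57989	58009
chrS	58989	59009
chrS	97989	98009
chrS	98989	99009
chrS	259999	260019
chrS	260739	260759
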