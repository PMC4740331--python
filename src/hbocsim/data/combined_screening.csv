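population,record,stratum,count
combined,funnel,screened,96055
combined,funnel,informative,92127
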