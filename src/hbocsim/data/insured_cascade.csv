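population,record,stratum,count
insured,funnel,screened,34131
insured,funnel,carriers_detected,36
insured,funnel,carriers_expected,47
insured,affected,prior,3
insured,affected,concomitant,2
insured,affected,unaffected,4
insured,stage,ovarian:III,2
insured,stage,breast:0,3
insured,stage,breast:I,4
insured,stage,breast:II,3
insured,stage,breast:unknown,1
insured,oophorectomy_elected,new,5
insured,oophorectomy_eligible,new,7
insured,oophorectomy_elected,prior_identified,10
insured,oophorectomy_eligible,prior_identified,14
insured,metadata,nccn_surveillance_compliance_pct,72
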