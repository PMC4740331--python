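population,record,stratum,count
underserved,funnel,screened,61924
underserved,funnel,attended,589
underserved,funnel,tested,446
underserved,funnel,carriers_detected,20
underserved,funnel,carriers_expected,85
underserved,affected,prior,7
underserved,affected,concomitant,5
underserved,affected,unaffected,8
underserved,stage,ovarian:III,4
underserved,stage,breast:I,1
underserved,stage,breast:II,1
underserved,stage,breast:III,4
underserved,stage,breast:IV,1
underserved,stage,breast:unknown,1
underserved,mastectomy_elected,affected,3
underserved,mastectomy_eligible,affected,8
underserved,mastectomy_elected,unaffected,1
underserved,mastectomy_eligible,unaffected,8
underserved,oophorectomy_elected,new,2
underserved,oophorectomy_eligible,new,5
underserved,metadata,nccn_surveillance_compliance_pct,39
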