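section,label,denom,count,printed_pct,note
pain,pain_last_year,195,166,85,
pain,difficult_activities,163,136,84,discrepant
pain,caused_by_work,165,114,69,
pain,missed_workdays,159,41,26,
pain,seen_physician,159,68,43,
pain,prescribed_opioid,68,21,31,
training,opioid_risk_training,179,99,53,discrepant
strategies,otc_medications,166,134,81,
strategies,health_practitioner,166,64,39,
strategies,other_strategies,166,49,30,
strategies,stop_task,166,35,21,
strategies,time_off,166,27,16,
strategies,meds_someone_else,166,20,12,
strategies,tell_supervisor,166,15,9,
benefits,no_onsite_nursing,163,144,88,
benefits,no_paid_sick_leave,165,119,74,discrepant
benefits,no_eap_mandatory,157,115,73,
benefits,no_paid_vacation,164,96,58,discrepant
benefits,no_unpaid_leave,153,88,57,discrepant
benefits,no_paid_disability,166,98,55,discrepant
benefits,no_eap_personal,164,76,46,
benefits,no_onsite_first_aid,159,51,32,
benefits,no_health_insurance,168,7,4,
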