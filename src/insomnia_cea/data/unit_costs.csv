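resource_id,label,unit_cost,year_of_data
gp,General Practitioner,48.89,2009
spec_initial,Specialist Physician initial,222.22,2009
spec_followup,Specialist Physician follow up,99.56,2009
psychologist,Psychologist,88.89,2009
health_prac,Health Practitioner,120.00,2009
alt_health_prac,Alternative Health Practitioner,75.56,2008
rx,Prescription medicine,6.42,2009
otc,Non prescription medicine,16.00,2009
transport,Transport for treatment (round trip),16.71,2009
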