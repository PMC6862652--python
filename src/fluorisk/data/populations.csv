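name,ir_L_per_day,ef_days_per_year,ed_years,bw_kg,at_days
men,2,365,40,78,14600
women,2,365,40,65,14600
children,1,365,6,14.5,2190
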