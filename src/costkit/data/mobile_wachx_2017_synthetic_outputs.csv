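facility_id,arm,beneficiaries,automated_messages,nurse_messages,clients_served_annual
facility_A,two_way,76,4425,993,152
facility_B,two_way,39,2499,393,80
facility_A,one_way,76,4604,0,152
facility_B,one_way,41,2714,0,80
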