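id,facility_id,arm,activity,input_category,cost_nature,quantity,quantity_unit,unit_price,currency,useful_life_years,shared_scope,research_flag
proj-two_way-system-development,PROJECT,two_way,system_development,startup,one_time,1.0,lump sum,12305.909214830972,USD,5.0,project,false
proj-two_way-hosting-platform,PROJECT,two_way,communication_delivery,communication,recurrent,12.0,month,33.333333333333336,USD,,project,false
proj-two_way-supervision__study_coordinator,PROJECT,two_way,supervision_coordination,personnel,recurrent,12.0,person-month,25.0,USD,,project,false
facility_A-two_way-planning,facility_A,two_way,planning,startup,one_time,1.0,lump sum,270.0,USD,5.0,facility,false
facility_A-two_way-initial_training,facility_A,two_way,initial_training,startup,one_time,1.0,lump sum,490.0,USD,5.0,facility,false
facility_A-two_way-sensitization,facility_A,two_way,sensitization,startup,one_time,1.0,lump sum,320.0,USD,5.0,facility,false
facility_A-two_way-equipment,facility_A,two_way,service_delivery,equipment,one_time,1.0,bundle,3250.0072808115933,USD,10.0,facility,false
facility_A-two_way-service-delivery__study_nurse,facility_A,two_way,service_delivery,personnel,recurrent,1.0790619450525238,person-month,123900.0,KES,,facility,false
facility_A-two_way-service-delivery__retention_officer,facility_A,two_way,service_delivery,personnel,recurrent,0.9249102386164492,person-month,61950.0,KES,,facility,false
facility_A-two_way-sms-airtime,facility_A,two_way,communication_delivery,communication,recurrent,5418.0,message,8.53084848038046,KES,,facility,false
facility_A-two_way-indirect-costs,facility_A,two_way,overhead_admin,overhead,recurrent,1.0,lump sum,3.0,USD,,facility,false
facility_B-two_way-planning,facility_B,two_way,planning,startup,one_time,1.0,lump sum,270.0,USD,5.0,facility,false
facility_B-two_way-initial_training,facility_B,two_way,initial_training,startup,one_time,1.0,lump sum,490.0,USD,5.0,facility,false
facility_B-two_way-sensitization,facility_B,two_way,sensitization,startup,one_time,1.0,lump sum,320.0,USD,5.0,facility,false
facility_B-two_way-equipment,facility_B,two_way,service_delivery,equipment,one_time,1.0,bundle,3250.0072808115933,USD,10.0,facility,false
facility_B-two_way-service-delivery__study_nurse,facility_B,two_way,service_delivery,personnel,recurrent,0.8629074542603634,person-month,123900.0,KES,,facility,false
facility_B-two_way-service-delivery__retention_officer,facility_B,two_way,service_delivery,personnel,recurrent,0.7396349607945975,person-month,61950.0,KES,,facility,false
facility_B-two_way-sms-airtime,facility_B,two_way,communication_delivery,communication,recurrent,2892.0,message,8.53084848038046,KES,,facility,false
facility_B-two_way-indirect-costs,facility_B,two_way,overhead_admin,overhead,recurrent,1.0,lump sum,3.0,USD,,facility,false
facility_B-two_way-clinic-collaboration-fee,facility_B,two_way,overhead_admin,overhead,recurrent,12.0,month,24.0,USD,,facility,false
proj-one_way-system-development,PROJECT,one_way,system_development,startup,one_time,1.0,lump sum,12298.410194174758,USD,5.0,project,false
proj-one_way-hosting-platform,PROJECT,one_way,communication_delivery,communication,recurrent,12.0,month,33.333333333333336,USD,,project,false
proj-one_way-supervision__study_coordinator,PROJECT,one_way,supervision_coordination,personnel,recurrent,12.0,person-month,25.0,USD,,project,false
facility_A-one_way-planning,facility_A,one_way,planning,startup,one_time,1.0,lump sum,265.0,USD,5.0,facility,false
facility_A-one_way-initial_training,facility_A,one_way,initial_training,startup,one_time,1.0,lump sum,490.0,USD,5.0,facility,false
facility_A-one_way-sensitization,facility_A,one_way,sensitization,startup,one_time,1.0,lump sum,320.0,USD,5.0,facility,false
facility_A-one_way-equipment,facility_A,one_way,service_delivery,equipment,one_time,1.0,bundle,3250.0072808115933,USD,10.0,facility,false
facility_A-one_way-service-delivery__study_nurse,facility_A,one_way,service_delivery,personnel,recurrent,0.5355099946829415,person-month,123900.0,KES,,facility,false
facility_A-one_way-service-delivery__retention_officer,facility_A,one_way,service_delivery,personnel,recurrent,0.45900856687109276,person-month,61950.0,KES,,facility,false
facility_A-one_way-sms-airtime,facility_A,one_way,communication_delivery,communication,recurrent,4604.0,message,4.412899382264263,KES,,facility,false
facility_A-one_way-indirect-costs,facility_A,one_way,overhead_admin,overhead,recurrent,1.0,lump sum,3.0,USD,,facility,false
facility_B-one_way-planning,facility_B,one_way,planning,startup,one_time,1.0,lump sum,265.0,USD,5.0,facility,false
facility_B-one_way-initial_training,facility_B,one_way,initial_training,startup,one_time,1.0,lump sum,490.0,USD,5.0,facility,false
facility_B-one_way-sensitization,facility_B,one_way,sensitization,startup,one_time,1.0,lump sum,320.0,USD,5.0,facility,false
facility_B-one_way-equipment,facility_B,one_way,service_delivery,equipment,one_time,1.0,bundle,3250.0072808115933,USD,10.0,facility,false
facility_B-one_way-service-delivery__study_nurse,facility_B,one_way,service_delivery,personnel,recurrent,0.26514619643247517,person-month,123900.0,KES,,facility,false
facility_B-one_way-service-delivery__retention_officer,facility_B,one_way,service_delivery,personnel,recurrent,0.22726816837069308,person-month,61950.0,KES,,facility,false
facility_B-one_way-sms-airtime,facility_B,one_way,communication_delivery,communication,recurrent,2714.0,message,4.412899382264263,KES,,facility,false
facility_B-one_way-indirect-costs,facility_B,one_way,overhead_admin,overhead,recurrent,1.0,lump sum,3.0,USD,,facility,false
facility_B-one_way-clinic-collaboration-fee,facility_B,one_way,overhead_admin,overhead,recurrent,12.0,month,24.0,USD,,facility,false
facility_A-clinic-collaboration-fee,facility_A,both,overhead_admin,overhead,recurrent,12.0,month,48.0,USD,,facility,false
research-international-staff-time,PROJECT,both,supervision_coordination,personnel,recurrent,2.0,person-month,9000.0,USD,,project,true
facility_A-research-time-motion-study,facility_A,both,overhead_admin,overhead,recurrent,1.0,study,1500.0,USD,,facility,true
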