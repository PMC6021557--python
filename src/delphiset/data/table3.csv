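item_id,text,category,pct_7to9,pct_1to3,median,iqr_low,iqr_high
hosp_other_procedures_n,Number of other procedures undergone,hospital,35.56,20.00,6,4,7
hosp_lab_tests_n,Number of laboratory tests undergone,hospital,35.56,24.44,5,4,7
hosp_imaging_type,Type of imaging scans undergone,hospital,31.11,15.56,6,5,8
hosp_other_procedures_type,Type of other procedures undergone,hospital,26.67,17.78,5,4,7
hosp_lab_tests_type,Type of laboratory tests undergone,hospital,22.22,26.67,5,3,6
outpatient_appt_length,Length of outpatient appointment,hospital,15.56,55.56,3,2,5
hospital_transport,Number of hospital transport journeys (nonemergency),hospital,13.33,42.22,5,2,5
ambulance_journeys,Number of ambulance journeys,emergency,28.89,17.78,5,4,7
time_in_ae,Time spent in A&E,emergency,15.56,46.67,4,3,5
gp_lab_tests_n,Number of laboratory tests undergone,gp_clinic,40.00,22.22,5,4,7
gp_minor_surgery_type,Type of minor surgery/procedures/treatments undergone,gp_clinic,33.33,11.11,5,5,7
gp_appt_timing,Timing of appointments (office hours or out of hours),gp_clinic,33.33,31.11,5,3,9
gp_lab_tests_type,Type of laboratory tests undergone,gp_clinic,26.67,28.89,5,3,7
home_equipment_type,Type of equipment or adaptation supplied,home,35.56,22.22,5,4,7
home_time_with_professional,Time spent with professional at home,home,33.33,22.22,5,4,7
home_time_daily_activities,Time spent by professional for help with daily activities,home,31.11,15.56,5,5,7
remote_contact_duration,Duration of contact with professional,remote,24.44,33.33,5,3,6
email_sms_contacts,Number of email or SMS (text) communications with health care professional,remote,13.33,42.22,4,3,5
community_support_services,Use of patient support services in the community (e.g. self-help groups/lunch clubs/day center),community,28.89,15.56,5,4,7
community_support_type,Type of support service used,community,24.44,22.22,5,4,6
date_moved_nursing_home,Date moved to nursing home,residential,46.67,13.33,6,5,9
date_moved_residential_home,Date moved to residential home,residential,42.22,13.33,6,5,9
date_moved_supported_accommodation,Date moved to supported accommodation/sheltered housing,residential,40.00,13.33,5,5,9
medication_frequency,Frequency taken,medication,42.22,15.56,6,5,9
medication_dose,Dose taken,medication,42.22,15.56,6,5,9
medication_route,Route taken (e.g. oral/suppository/intravenous),medication,24.44,35.56,5,3,6
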