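item_id,text,category,pct_7to9,pct_1to3,median,iqr_low,iqr_high,printed_label
hospital_admissions,Number of hospital admissions (inpatient stay or day case),hospital,95.56,0.00,9,9,9,Consensus
hospital_outpatients,Number of hospital outpatient appointments,hospital,91.11,2.22,9,8,9,Consensus
length_of_stay,Length of stay (e.g. dates or number of nights),hospital,84.44,0.00,9,8,9,Consensus
operation_procedure,Number of operations/procedures undergone,hospital,64.44,4.44,8,6,9,Consensus
operation_type,Type of operation/procedure undergone,hospital,64.44,4.44,8,6,9,Consensus
professional_seen_outpatient,Type of professional seen (e.g. consultant/nurse),hospital,53.33,13.33,7,5,8,Consensus
imaging_scans,Number of imaging scans undergone (e.g. x-ray/MRI),hospital,42.22,13.33,6,5,8,Top 10
specialty_ward,Type of ward stayed in,hospital,37.78,11.11,6,5,8,Top 10
ae_visits,Number of visits to A&E,emergency,91.11,0.00,9,7,9,Consensus
admissions_after_ae,"Number of admissions to hospital, after A&E",emergency,80.00,2.22,9,7,9,Consensus
paramedic_care,Number of times paramedic care received,emergency,53.33,4.44,7,5,9,Consensus
gp_appointments,Number of appointments at a GP surgery or health clinic,gp_clinic,95.56,2.22,9,9,9,Consensus
gp_professional_seen,Type of professional seen (e.g. GP/nurse/counselor),gp_clinic,80.00,0.00,9,7,9,Consensus
gp_minor_surgery,Number of minor surgery/procedures/treatments undergone,gp_clinic,46.67,6.67,6,5,9,Subgroup
home_visits,Number of health care or social care professional visits at home (e.g. health visitor/GP),home,86.67,2.22,9,8,9,Consensus
professional_seen_at_home,Type of professional seen at home,home,80.00,0.00,9,7,9,Consensus
help_with_activities,Number of professional visits for help with daily activities (e.g. washing/dressing),home,55.56,6.67,7,5,9,Consensus
equipment,Equipment (e.g. wheelchairs/portable oxygen/specialist clothing) or home adaptation (e.g. grab rails/ramp) supplied,home,44.44,13.33,6,5,8,Close
telephone_computer_contacts,Number of real-time telephone/computer contacts with health or social care professional (e.g. with GP or telephone helpline),remote,68.89,4.44,7,6,9,Consensus
professional_contacted,Type of professional contacted (e.g. doctor/nurse/social worker),remote,53.33,6.67,7,5,9,Consensus
community_health_care,"Number of visits to health care professional in the community (e.g. dentist, pharmacist, nurse, counselor, and therapist)",community,80.00,2.22,9,7,9,Consensus
community_social_care,Number of visits to social care professional in the community (e.g. social worker/housing worker/drug and alcohol worker),community,75.56,2.22,9,7,9,Consensus
health_professional_seen,Type of health care professional seen,community,71.11,4.44,8,5,9,Consensus
social_care_professional_seen,Type of social care professional seen in the community,community,62.22,4.44,8,5,9,Consensus
stay_in_hospice,Stay in hospice,residential,77.78,6.67,9,7,9,Consensus
hospice_length_of_stay,Length of time spent in the hospice,residential,75.56,8.89,8,7,9,Consensus
respite_care,Use of short-term respite or rehabilitation care,residential,66.67,6.67,7,5,9,Consensus
respite_length_of_stay,Length of stay in short-term respite or rehabilitation care,residential,62.22,8.89,7,5,9,Consensus
nursing_home,Living in a nursing home,residential,53.33,11.11,7,5,9,Consensus
residential_home,Living in a residential home,residential,48.89,11.11,6,5,9,Subgroup
supported_accommodation,Living in supported accommodation/sheltered housing,residential,46.67,11.11,6,5,9,Subgroup
prescribed_medication,Number of prescribed medications,medication,68.89,6.67,8,5,9,Consensus
name_of_medication,Name of medication,medication,64.44,4.44,8,5,9,Consensus
period_taken_for,Period taken for (e.g. dates or number of days),medication,46.67,11.11,6,5,9,Subgroup
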