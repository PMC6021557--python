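item_id,text,pct_7to9,pct_8or9,pct_1to3,preagreed,stringent,final_outcome
hospital_outpatients,Hospital outpatients,97.62,80.95,0.00,Include,Include,Short form
hospital_admissions,Hospital admissions,97.62,90.48,2.38,Include,Include,Short form
length_of_stay,Length of stay,92.86,85.71,2.38,Include,Include,Short form
operation_procedure,Operation/procedure,78.57,61.90,0.00,Include,Exclude,Extended hospital care module
operation_type,Operation type,71.43,54.76,0.00,Include,Exclude,Extended hospital care module
ae_visits,A&E,95.24,88.10,0.00,Include,Include,Short form
admissions_after_ae,Admissions after A&E,88.10,76.19,7.14,Include,Include,Short form
gp_appointments,GP appointments,97.62,95.24,0.00,Include,Include,Short form
gp_professional_seen,GP professional seen,92.86,78.57,0.00,Include,Include,Short form
home_visits,Home visits,97.62,85.71,0.00,Include,Include,Short form
professional_seen_at_home,Professional seen at home,88.10,69.05,2.38,Include,Exclude,Short form
community_health_care,Community health care,88.10,78.57,2.38,Include,Include,Combined with GP appointments in short form
community_social_care,Community social care,85.71,69.05,0.00,Include,Exclude,Social care module
health_professional_seen,Health professional seen,78.57,57.14,2.38,Include,Exclude,Combined with GP appointments in short form
social_care_professional_seen,Social care professional seen,73.81,52.38,2.38,Include,Exclude,Social care module
stay_in_hospice,Stay in hospice,80.95,73.81,9.52,Include,Include,Residential care module
hospice_length_of_stay,Hospice length of stay,78.57,66.67,11.90,Include,Exclude,Residential care module
respite_care,Respite care,73.81,40.48,7.14,Include,Exclude,Residential care module
name_of_medication,Name of medication,73.81,59.52,4.76,Include,Exclude,Short form
professional_seen_outpatient,Professional seen outpatient,57.14,26.19,4.76,Exclude,Exclude,
specialty_ward,Specialty/ward,38.10,16.67,9.52,Exclude,Exclude,
imaging_scans,Imaging scans,23.81,11.90,9.52,Exclude,Exclude,
paramedic_care,Paramedic care,50.00,23.81,0.00,Exclude,Exclude,
gp_minor_surgery,GP surgery/procedure,35.71,16.67,9.52,Exclude,Exclude,
help_with_activities,Help with activities,59.52,30.95,2.38,Exclude,Exclude,
equipment,Equipment,33.33,21.43,2.38,Exclude,Exclude,
telephone_computer_contacts,Telephone/computer contacts,64.29,38.10,2.38,Exclude,Exclude,
professional_contacted,Professional contacted,54.76,35.71,2.38,Exclude,Exclude,
respite_length_of_stay,Respite length of stay,64.29,40.48,7.14,Exclude,Exclude,
nursing_home,Nursing home,57.14,35.71,9.52,Exclude,Exclude,
residential_home,Residential home,40.48,28.57,11.90,Exclude,Exclude,
supported_accommodation,Supported accommodation,30.95,19.05,11.90,Exclude,Exclude,
prescribed_medication,Prescribed medication,64.29,47.62,14.29,Exclude,Exclude,
period_taken_for,Period taken for,40.48,28.57,4.76,Exclude,Exclude,
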