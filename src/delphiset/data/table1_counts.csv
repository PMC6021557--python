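characteristic,level,n,pct
experience,lt5,11,24.4
experience,5to10,12,26.7
experience,10to20,11,24.4
experience,gt20,11,24.4
trial_experience,adults,44,97.8
trial_experience,children,21,46.7
trial_experience,older_adults,26,57.8
trial_experience,physical,38,84.4
trial_experience,mental,28,62.2
trial_experience,public_health,20,44.4
trial_experience,primary_care,33,73.3
trial_experience,secondary_care,39,86.7
background,academia,42,93.3
background,other,3,6.7
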