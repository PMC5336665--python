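column,type,range_or_values,missing_encoding,description
participant_id,string,any,never missing,opaque participant identifier
sex,categorical,male|female,never missing,sex used for norm stratification
age_years,integer,>=0,never missing,age in years at wave 4
education_years,integer,>=0,never missing,completed years of education (bands: <10 low; 10-14 medium; 15+ high)
<test>_w3,real,test-specific,empty cell,raw score of a battery test at wave 3 (tests: sdmt trails_a reaction_time_simple reaction_time_choice digits_backward trails_b stroop cvlt_immediate cvlt_delayed bvrt cowat bnt15 spot_the_word purdue_pegboard iat rmet)
<test>_w4,real,test-specific,empty cell,raw score of the same test at wave 4
mmse_w3,integer,0-30,empty cell,Mini-Mental State Examination total at wave 3
mmse_w4,integer,0-30,empty cell,Mini-Mental State Examination total at wave 4
macq_total,integer,7-35,empty cell,Memory and Cognition Questionnaire total (>24 = subjective decline)
phq9_total,integer,0-27,empty cell,Patient Health Questionnaire depression screen (>=10 excludes)
hrs_iadl_memory_problem,tristate,yes|no|empty,empty cell,self-reported IADL problems due to memory
needs_care_help,tristate,yes|no|empty,empty cell,self-reported need for household/personal care help
informant_available,boolean,yes|no,never missing,whether an informant interview exists; no forces all informant fields empty
iqcode_mean,real,1-5,empty cell,informant questionnaire of cognitive decline mean (>3.31 = observed decline)
bayer_iadl_mean,real,1-10,empty cell,Bayer IADL scale mean (>3.12 = functional interference)
bayer_item2_difficulty,tristate,yes|no|empty,empty cell,informant-reported difficulty on Bayer item 2
bayer_item4_difficulty,tristate,yes|no|empty,empty cell,informant-reported difficulty on Bayer item 4
bayer_item11_difficulty,tristate,yes|no|empty,empty cell,informant-reported difficulty on Bayer item 11
dexq_item9,ordinal,0-4,empty cell,DEX-Q item 9 frequency (0 never .. 4 very often; >=2 = sometimes or more)
dexq_item11,ordinal,0-4,empty cell,DEX-Q item 11 frequency
dexq_item13,ordinal,0-4,empty cell,DEX-Q item 13 frequency
dexq_item20,ordinal,0-4,empty cell,DEX-Q item 20 frequency
flag_behave_out_of_character,tristate,yes|no|empty,empty cell,informant endorsement: behaves out of character or inappropriately
flag_unaware_others_feelings,tristate,yes|no|empty,empty cell,informant endorsement: unconcerned/unaware of how others feel
flag_less_social_participation,tristate,yes|no|empty,empty cell,informant endorsement: less participation in social functions (non-physical reasons)
flag_lost_skills_hobbies,tristate,yes|no|empty,empty cell,informant endorsement: lost special skills interests or hobbies
flag_difficulty_familiar_tasks,tristate,yes|no|empty,empty cell,informant endorsement: difficulty with familiar tasks (parking assembling sewing)
flag_difficulty_familiar_tools,tristate,yes|no|empty,empty cell,informant endorsement: difficulty using familiar tools or equipment
flag_lost_in_familiar_places,tristate,yes|no|empty,empty cell,informant endorsement: gets lost in familiar places
informant_worsening,tristate,yes|no|empty,empty cell,informant reports worsening of everyday cognitive function
doctor_consult_cognition,tristate,yes|no|empty,empty cell,recent doctor's consultation about cognitive change
history_psychosis,tristate,yes|no|empty,empty cell,informant-reported history of schizophrenia or other psychosis
prior_path_diagnosis,categorical,none|mci_like|dementia,never missing (defaults none),previous study diagnosis used by Screen 1
onset_months_ago,real,>=0,empty cell,informant-reported months since cognitive deficits started
delirium_signs,tristate,yes|no|empty,empty cell,informant-reported signs of delirium
delirium_duration_months,real,>=0,empty cell,duration of delirium signs in months
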