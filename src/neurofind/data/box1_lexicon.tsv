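surface	category	concept
infarct	sbi_finding	sbi
infarcts	sbi_finding	sbi
infarctions	sbi_finding	sbi
infarction	sbi_finding	sbi
lacune	sbi_finding	sbi
lacunes	sbi_finding	sbi
acute	sbi_modifier_acute	sbi
acute or subacute	sbi_modifier_acute	sbi
recent	sbi_modifier_acute	sbi
new	sbi_modifier_acute	sbi
remote	sbi_modifier_chronic	sbi
old	sbi_modifier_chronic	sbi
chronic	sbi_modifier_chronic	sbi
prior	sbi_modifier_chronic	sbi
chronic foci of	sbi_modifier_chronic	sbi
benign	sbi_modifier_chronic	sbi
stable small	sbi_modifier_chronic	sbi
stable	sbi_modifier_chronic	sbi
territorial	sbi_location	sbi
lacunar	sbi_location	sbi
cerebellar	sbi_location	sbi
cortical	sbi_location	sbi
frontal	sbi_location	sbi
caudate	sbi_location	sbi
right frontoparietal lobe	sbi_location	sbi
right frontal cortical	sbi_location	sbi
right frontal lobe	sbi_location	sbi
embolic	sbi_location	sbi
left basal ganglia lacunar	sbi_location	sbi
basal ganglia lacunar	sbi_location	sbi
left caudate and left putamen lacunar	sbi_location	sbi
leukoaraiosis	wmd_finding	wmd
white matter	wmd_finding	wmd
microvascular ischemic	wmd_finding	wmd
microvascular leukemic	wmd_finding	wmd
microvascular degenerative	wmd_finding	wmd
degenerative changes	wmd_exclusion	wmd
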