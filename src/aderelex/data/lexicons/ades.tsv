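colitis	colitis
pneumonitis	pneumonitis
thyroid abnormalities	thyroid abnormalities|thyroid abnormality|hypothyroidism|hyperthyroidism|thyroiditis
rash/dermatitis	rash|dermatitis
hepatitis	hepatitis|transaminitis
myalgia/arthralgia	myalgia|arthralgia
cardiotoxicity	cardiotoxicity|myocarditis
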