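gene	function_category	traits
DGKH	Intracellular signaling pathway	Neuroticism;Openness
FAAH	Intracellular signaling pathway	Neuroticism
ANKK1	Dopaminergic signaling system	Neuroticism;Extraversion
DRD2	Dopaminergic signaling system	Neuroticism
HTR2A	Serotonergic signaling system	Neuroticism
SLC6A4	Serotonergic signaling system	Neuroticism
COMT	Monoamine inactivation enzyme	Agreeableness;Conscientiousness;Extraversion;Neuroticism;Openness
MAOA	Monoamine inactivation enzyme	Neuroticism
GABRA6	GABAergic signaling system	Neuroticism
CNR1	Endogenous cannabinoid signaling system	Neuroticism;Agreeableness
LEP	Peptide neurotransmission	Neuroticism
NPY	Peptide neurotransmission	Neuroticism;Conscientiousness
P2RX7	Purinergic signaling system	Neuroticism
HSD11B1	Hypothalamic-pituitary-adrenal axis	Neuroticism
APOE	Neurotrophic-related factor	Neuroticism
BDNF	Neurotrophic-related factor	Neuroticism
CDH13	Intercellular connections	Neuroticism;Agreeableness
PER3	Circadian rhythm	Neuroticism;Extraversion
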