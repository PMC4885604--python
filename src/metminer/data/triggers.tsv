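# Bundled trigger lexicon: surface<TAB>trigger_class
# Triggers are verbs or nominal verbs; adverbs are rejected at load time.
induce	POSITIVE_REG
promote	POSITIVE_REG
enhance	POSITIVE_REG
activate	POSITIVE_REG
upregulate	POSITIVE_REG
stimulate	POSITIVE_REG
increase	POSITIVE_REG
facilitate	POSITIVE_REG
accelerate	POSITIVE_REG
drive	POSITIVE_REG
inhibit	NEGATIVE_REG
suppress	NEGATIVE_REG
repress	NEGATIVE_REG
downregulate	NEGATIVE_REG
reduce	NEGATIVE_REG
attenuate	NEGATIVE_REG
block	NEGATIVE_REG
abolish	NEGATIVE_REG
impair	NEGATIVE_REG
silence	NEGATIVE_REG
regulate	NEUTRAL_REG
modulate	NEUTRAL_REG
control	NEUTRAL_REG
affect	NEUTRAL_REG
mediate	NEUTRAL_REG
influence	NEUTRAL_REG
target	NEUTRAL_REG
metastasize	METASTASIS_TRIGGER
spread	METASTASIS_TRIGGER
disseminate	METASTASIS_TRIGGER
colonize	METASTASIS_TRIGGER
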