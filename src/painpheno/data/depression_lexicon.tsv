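term	kind
depression	concept
depressed	concept
depressive	concept
depressed mood	concept
depressive disorder	concept
major depressive disorder	concept
major depression	concept
depressive symptoms	concept
depressive episode	concept
dysthymia	concept
anhedonia	concept
low mood	concept
feeling down	concept
st depression	exclusion
st depressions	exclusion
st segment depression	exclusion
ecg depression	exclusion
respiratory depression	exclusion
depression fracture	exclusion
depressed fracture	exclusion
depressed skull fracture	exclusion
depression of the tibial plateau	exclusion
depression of the skull	exclusion
no	pre_neg
not	pre_neg
denies	pre_neg
denied	pre_neg
without	pre_neg
no symptoms of	pre_neg
no evidence of	pre_neg
no history of	pre_neg
no signs of	pre_neg
negative for	pre_neg
free of	pre_neg
absence of	pre_neg
never had	pre_neg
rules out	pre_neg
ruled out	post_neg
unlikely	post_neg
not present	post_neg
has resolved	post_neg
but	termination
however	termination
although	termination
though	termination
except	termination
nevertheless	termination
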