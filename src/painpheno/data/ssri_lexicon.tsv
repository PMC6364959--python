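term	kind
sertraline	concept
fluoxetine	concept
paroxetine	concept
citalopram	concept
escitalopram	concept
fluvoxamine	concept
zoloft	concept
prozac	concept
paxil	concept
celexa	concept
lexapro	concept
luvox	concept
no	pre_neg
not	pre_neg
denies	pre_neg
denied	pre_neg
without	pre_neg
never took	pre_neg
discontinued	pre_neg
stopped	pre_neg
off	pre_neg
allergic to	pre_neg
no longer taking	pre_neg
discontinued	post_neg
was stopped	post_neg
but	termination
however	termination
although	termination
though	termination
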