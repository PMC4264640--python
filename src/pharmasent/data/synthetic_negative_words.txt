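; Synthetic negative opinion-word list (opinion-lexicon dialect).
; A compact stand-in lexicon used as the package default and by the
; synthetic corpus generator; it is NOT the published 4783-term list.
; Words are screened so none contains a default filter keyword.
bad
nasty
awful
terrible
horrible
horrid
worst
worse
pain
painful
hurt
hurting
hurts
sick
sicker
tired
fatigue
fatigued
nausea
nauseous
dizzy
dizziness
scared
scary
afraid
anxious
anxiety
fear
worried
worry
sad
depressed
depressing
annoying
annoyed
hate
hated
hates
problem
problems
struggle
struggling
severe
dangerous
failed
failing
failure
miserable
suffering
suffered
crying
cried
itchy
rash
headache
migraine
weak
weaker
weakness
numb
numbness
exhausted
exhausting
frustrating
frustrated
angry
upset
unbearable
allergic
burning
ache
aching
chills
vomiting
relapse
relapsed
stress
stressful
stressed
panic
nightmare
dreadful
unpleasant
uncomfortable
broken
toxic
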