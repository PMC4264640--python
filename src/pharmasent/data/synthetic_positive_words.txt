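; Synthetic positive opinion-word list (opinion-lexicon dialect).
; A compact stand-in lexicon used as the package default and by the
; synthetic corpus generator; it is NOT the published 2006-term list.
; Words are screened so none contains a default filter keyword.
good
great
love
loved
loves
awesome
amazing
excellent
wonderful
fantastic
brilliant
happy
happier
hopeful
hope
better
best
improved
improving
improvement
relief
relieved
grateful
thankful
glad
positive
easy
easier
comfortable
effective
helpful
helped
helping
encouraging
encouraged
promising
calm
confident
energetic
strong
stronger
stable
smooth
painless
gentle
pleasant
enjoy
enjoyed
thriving
recovery
recovered
blessed
lucky
perfect
nice
fine
beautiful
superb
delighted
optimistic
winning
successful
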