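emoticon,word
:),good
:-),good
=),good
;),good
;-),good
:d,good
:p,good
<3,love
:(,bad
:-(,bad
=(,bad
:'(,bad
:-d,good
:/,bad
:-/,bad
</3,bad
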