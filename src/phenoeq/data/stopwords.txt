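# Default stop-word list: common English function words removed before
# dictionary matching.  One token per line.
the
of
in
a
an
to
and
or
with
for
on
by
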