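# Keywords marking repeat-associated gene models.
# A gene whose best-ranked hit description contains any of these
# (case-insensitive substring match) is removed from the annotation.
transposon
retrotransposon
transposase
gag
pol
polyprotein
reverse transcriptase
integrase
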