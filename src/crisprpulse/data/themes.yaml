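# Theme name -> case-insensitive regular expression.
# Stock set of six broad themes with simple stem patterns; replace this file
# (or pass --themes) to supply a curated table.
genome: "genom(e|es|ic|ics)"
baby: "bab(y|ies)"
disease: "disease|illness|disorder"
embryo: "embryo"
treatment: "treat(ment|ments|ing|ed)?|therap(y|ies|eutic)"
mutation: "mutat(e|es|ed|ing|ion|ions)"
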