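raw_value,category
abdominal,abdominal
abdominal pain,abdominal
nausea/vomiting,abdominal
chest,chest
chest pain,chest
palpitations,chest
respiratory,respiratory
shortness of breath,respiratory
cough,respiratory
neurological,neurological
headache,neurological
dizziness,neurological
weakness,neurological
visual field cut,neurological
musculoskeletal,musculoskeletal
back pain,musculoskeletal
extremity pain,musculoskeletal
fall,musculoskeletal
skin,skin
rash,skin
cellulitis,skin
laceration,skin
abscess,skin
urinary,urinary
dysuria,urinary
urinary retention,urinary
foley problem,urinary
eye,eye
eye pain,eye
eye redness,eye
foreign body eye,eye
other,other
fever,other
fatigue,other
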