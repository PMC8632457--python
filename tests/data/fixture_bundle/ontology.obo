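format-version: 1.2
ontology: disease-ontology

[Term]
id: T:R
name: T:R

[Term]
id: T:R.0
name: T:R.0
is_a: T:R

[Term]
id: T:R.0.0
name: T:R.0.0
is_a: T:R.0

[Term]
id: T:R.0.0.0
name: T:R.0.0.0
is_a: T:R.0.0

[Term]
id: T:R.0.0.0.0
name: T:R.0.0.0.0
is_a: T:R.0.0.0

[Term]
id: T:R.0.0.0.1
name: T:R.0.0.0.1
is_a: T:R.0.0.0

[Term]
id: T:R.0.0.0.2
name: T:R.0.0.0.2
is_a: T:R.0.0.0

[Term]
id: T:R.0.0.1
name: T:R.0.0.1
is_a: T:R.0.0

[Term]
id: T:R.0.0.1.0
name: T:R.0.0.1.0
is_a: T:R.0.0.1

[Term]
id: T:R.0.0.1.1
name: T:R.0.0.1.1
is_a: T:R.0.0.1

[Term]
id: T:R.0.0.1.2
name: T:R.0.0.1.2
is_a: T:R.0.0.1

[Term]
id: T:R.0.0.2
name: T:R.0.0.2
is_a: T:R.0.0

[Term]
id: T:R.0.0.2.0
name: T:R.0.0.2.0
is_a: T:R.0.0.2

[Term]
id: T:R.0.0.2.1
name: T:R.0.0.2.1
is_a: T:R.0.0.2

[Term]
id: T:R.0.0.2.2
name: T:R.0.0.2.2
is_a: T:R.0.0.2

[Term]
id: T:R.0.1
name: T:R.0.1
is_a: T:R.0

[Term]
id: T:R.0.1.0
name: T:R.0.1.0
is_a: T:R.0.1

[Term]
id: T:R.0.1.0.0
name: T:R.0.1.0.0
is_a: T:R.0.1.0

[Term]
id: T:R.0.1.0.1
name: T:R.0.1.0.1
is_a: T:R.0.1.0

[Term]
id: T:R.0.1.0.2
name: T:R.0.1.0.2
is_a: T:R.0.1.0

[Term]
id: T:R.0.1.1
name: T:R.0.1.1
is_a: T:R.0.1

[Term]
id: T:R.0.1.1.0
name: T:R.0.1.1.0
is_a: T:R.0.1.1

[Term]
id: T:R.0.1.1.1
name: T:R.0.1.1.1
is_a: T:R.0.1.1

[Term]
id: T:R.0.1.1.2
name: T:R.0.1.1.2
is_a: T:R.0.1.1

[Term]
id: T:R.0.1.2
name: T:R.0.1.2
is_a: T:R.0.1

[Term]
id: T:R.0.1.2.0
name: T:R.0.1.2.0
is_a: T:R.0.1.2

[Term]
id: T:R.0.1.2.1
name: T:R.0.1.2.1
is_a: T:R.0.1.2

[Term]
id: T:R.0.1.2.2
name: T:R.0.1.2.2
is_a: T:R.0.1.2

[Term]
id: T:R.0.2
name: T:R.0.2
is_a: T:R.0

[Term]
id: T:R.0.2.0
name: T:R.0.2.0
is_a: T:R.0.2

[Term]
id: T:R.0.2.0.0
name: T:R.0.2.0.0
is_a: T:R.0.2.0

[Term]
id: T:R.0.2.0.1
name: T:R.0.2.0.1
is_a: T:R.0.2.0

[Term]
id: T:R.0.2.0.2
name: T:R.0.2.0.2
is_a: T:R.0.2.0

[Term]
id: T:R.0.2.1
name: T:R.0.2.1
is_a: T:R.0.2

[Term]
id: T:R.0.2.1.0
name: T:R.0.2.1.0
is_a: T:R.0.2.1

[Term]
id: T:R.0.2.1.1
name: T:R.0.2.1.1
is_a: T:R.0.2.1

[Term]
id: T:R.0.2.1.2
name: T:R.0.2.1.2
is_a: T:R.0.2.1

[Term]
id: T:R.0.2.2
name: T:R.0.2.2
is_a: T:R.0.2

[Term]
id: T:R.0.2.2.0
name: T:R.0.2.2.0
is_a: T:R.0.2.2

[Term]
id: T:R.0.2.2.1
name: T:R.0.2.2.1
is_a: T:R.0.2.2

[Term]
id: T:R.0.2.2.2
name: T:R.0.2.2.2
is_a: T:R.0.2.2

[Term]
id: T:R.1
name: T:R.1
is_a: T:R

[Term]
id: T:R.1.0
name: T:R.1.0
is_a: T:R.1

[Term]
id: T:R.1.0.0
name: T:R.1.0.0
is_a: T:R.1.0

[Term]
id: T:R.1.0.0.0
name: T:R.1.0.0.0
is_a: T:R.1.0.0

[Term]
id: T:R.1.0.0.1
name: T:R.1.0.0.1
is_a: T:R.1.0.0

[Term]
id: T:R.1.0.0.2
name: T:R.1.0.0.2
is_a: T:R.1.0.0

[Term]
id: T:R.1.0.1
name: T:R.1.0.1
is_a: T:R.1.0

[Term]
id: T:R.1.0.1.0
name: T:R.1.0.1.0
is_a: T:R.1.0.1

[Term]
id: T:R.1.0.1.1
name: T:R.1.0.1.1
is_a: T:R.1.0.1

[Term]
id: T:R.1.0.1.2
name: T:R.1.0.1.2
is_a: T:R.1.0.1

[Term]
id: T:R.1.0.2
name: T:R.1.0.2
is_a: T:R.1.0

[Term]
id: T:R.1.0.2.0
name: T:R.1.0.2.0
is_a: T:R.1.0.2

[Term]
id: T:R.1.0.2.1
name: T:R.1.0.2.1
is_a: T:R.1.0.2

[Term]
id: T:R.1.0.2.2
name: T:R.1.0.2.2
is_a: T:R.1.0.2

[Term]
id: T:R.1.1
name: T:R.1.1
is_a: T:R.1

[Term]
id: T:R.1.1.0
name: T:R.1.1.0
is_a: T:R.1.1

[Term]
id: T:R.1.1.0.0
name: T:R.1.1.0.0
is_a: T:R.1.1.0

[Term]
id: T:R.1.1.0.1
name: T:R.1.1.0.1
is_a: T:R.1.1.0

[Term]
id: T:R.1.1.0.2
name: T:R.1.1.0.2
is_a: T:R.1.1.0

[Term]
id: T:R.1.1.1
name: T:R.1.1.1
is_a: T:R.1.1

[Term]
id: T:R.1.1.1.0
name: T:R.1.1.1.0
is_a: T:R.1.1.1

[Term]
id: T:R.1.1.1.1
name: T:R.1.1.1.1
is_a: T:R.1.1.1

[Term]
id: T:R.1.1.1.2
name: T:R.1.1.1.2
is_a: T:R.1.1.1

[Term]
id: T:R.1.1.2
name: T:R.1.1.2
is_a: T:R.1.1

[Term]
id: T:R.1.1.2.0
name: T:R.1.1.2.0
is_a: T:R.1.1.2

[Term]
id: T:R.1.1.2.1
name: T:R.1.1.2.1
is_a: T:R.1.1.2

[Term]
id: T:R.1.1.2.2
name: T:R.1.1.2.2
is_a: T:R.1.1.2

[Term]
id: T:R.1.2
name: T:R.1.2
is_a: T:R.1

[Term]
id: T:R.1.2.0
name: T:R.1.2.0
is_a: T:R.1.2

[Term]
id: T:R.1.2.0.0
name: T:R.1.2.0.0
is_a: T:R.1.2.0

[Term]
id: T:R.1.2.0.1
name: T:R.1.2.0.1
is_a: T:R.1.2.0

[Term]
id: T:R.1.2.0.2
name: T:R.1.2.0.2
is_a: T:R.1.2.0

[Term]
id: T:R.1.2.1
name: T:R.1.2.1
is_a: T:R.1.2

[Term]
id: T:R.1.2.1.0
name: T:R.1.2.1.0
is_a: T:R.1.2.1

[Term]
id: T:R.1.2.1.1
name: T:R.1.2.1.1
is_a: T:R.1.2.1

[Term]
id: T:R.1.2.1.2
name: T:R.1.2.1.2
is_a: T:R.1.2.1

[Term]
id: T:R.1.2.2
name: T:R.1.2.2
is_a: T:R.1.2

[Term]
id: T:R.1.2.2.0
name: T:R.1.2.2.0
is_a: T:R.1.2.2

[Term]
id: T:R.1.2.2.1
name: T:R.1.2.2.1
is_a: T:R.1.2.2

[Term]
id: T:R.1.2.2.2
name: T:R.1.2.2.2
is_a: T:R.1.2.2

[Term]
id: T:R.2
name: T:R.2
is_a: T:R

[Term]
id: T:R.2.0
name: T:R.2.0
is_a: T:R.2

[Term]
id: T:R.2.0.0
name: T:R.2.0.0
is_a: T:R.2.0

[Term]
id: T:R.2.0.0.0
name: T:R.2.0.0.0
is_a: T:R.2.0.0

[Term]
id: T:R.2.0.0.1
name: T:R.2.0.0.1
is_a: T:R.2.0.0

[Term]
id: T:R.2.0.0.2
name: T:R.2.0.0.2
is_a: T:R.2.0.0

[Term]
id: T:R.2.0.1
name: T:R.2.0.1
is_a: T:R.2.0

[Term]
id: T:R.2.0.1.0
name: T:R.2.0.1.0
is_a: T:R.2.0.1

[Term]
id: T:R.2.0.1.1
name: T:R.2.0.1.1
is_a: T:R.2.0.1

[Term]
id: T:R.2.0.1.2
name: T:R.2.0.1.2
is_a: T:R.2.0.1

[Term]
id: T:R.2.0.2
name: T:R.2.0.2
is_a: T:R.2.0

[Term]
id: T:R.2.0.2.0
name: T:R.2.0.2.0
is_a: T:R.2.0.2

[Term]
id: T:R.2.0.2.1
name: T:R.2.0.2.1
is_a: T:R.2.0.2

[Term]
id: T:R.2.0.2.2
name: T:R.2.0.2.2
is_a: T:R.2.0.2

[Term]
id: T:R.2.1
name: T:R.2.1
is_a: T:R.2

[Term]
id: T:R.2.1.0
name: T:R.2.1.0
is_a: T:R.2.1

[Term]
id: T:R.2.1.0.0
name: T:R.2.1.0.0
is_a: T:R.2.1.0

[Term]
id: T:R.2.1.0.1
name: T:R.2.1.0.1
is_a: T:R.2.1.0

[Term]
id: T:R.2.1.0.2
name: T:R.2.1.0.2
is_a: T:R.2.1.0

[Term]
id: T:R.2.1.1
name: T:R.2.1.1
is_a: T:R.2.1

[Term]
id: T:R.2.1.1.0
name: T:R.2.1.1.0
is_a: T:R.2.1.1

[Term]
id: T:R.2.1.1.1
name: T:R.2.1.1.1
is_a: T:R.2.1.1

[Term]
id: T:R.2.1.1.2
name: T:R.2.1.1.2
is_a: T:R.2.1.1

[Term]
id: T:R.2.1.2
name: T:R.2.1.2
is_a: T:R.2.1

[Term]
id: T:R.2.1.2.0
name: T:R.2.1.2.0
is_a: T:R.2.1.2

[Term]
id: T:R.2.1.2.1
name: T:R.2.1.2.1
is_a: T:R.2.1.2

[Term]
id: T:R.2.1.2.2
name: T:R.2.1.2.2
is_a: T:R.2.1.2

[Term]
id: T:R.2.2
name: T:R.2.2
is_a: T:R.2

[Term]
id: T:R.2.2.0
name: T:R.2.2.0
is_a: T:R.2.2

[Term]
id: T:R.2.2.0.0
name: T:R.2.2.0.0
is_a: T:R.2.2.0

[Term]
id: T:R.2.2.0.1
name: T:R.2.2.0.1
is_a: T:R.2.2.0

[Term]
id: T:R.2.2.0.2
name: T:R.2.2.0.2
is_a: T:R.2.2.0

[Term]
id: T:R.2.2.1
name: T:R.2.2.1
is_a: T:R.2.2

[Term]
id: T:R.2.2.1.0
name: T:R.2.2.1.0
is_a: T:R.2.2.1

[Term]
id: T:R.2.2.1.1
name: T:R.2.2.1.1
is_a: T:R.2.2.1

[Term]
id: T:R.2.2.1.2
name: T:R.2.2.1.2
is_a: T:R.2.2.1

[Term]
id: T:R.2.2.2
name: T:R.2.2.2
is_a: T:R.2.2

[Term]
id: T:R.2.2.2.0
name: T:R.2.2.2.0
is_a: T:R.2.2.2

[Term]
id: T:R.2.2.2.1
name: T:R.2.2.2.1
is_a: T:R.2.2.2

[Term]
id: T:R.2.2.2.2
name: T:R.2.2.2.2
is_a: T:R.2.2.2
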