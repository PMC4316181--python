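format-version: 1.2
ontology: mi
remark: Synthetic slim of the PSI-MI controlled vocabulary covering the interaction detection method and interaction type branches used by the default MIscore tables. Hierarchy (is_a paths) follows the public PSI-MI ontology; only the terms needed for score resolution are included.

[Term]
id: MI:0000
name: molecular interaction

[Term]
id: MI:0001
name: interaction detection method
is_a: MI:0000 ! molecular interaction

[Term]
id: MI:0045
name: experimental interaction detection
is_a: MI:0001 ! interaction detection method

[Term]
id: MI:0013
name: biophysical
is_a: MI:0045 ! experimental interaction detection

[Term]
id: MI:0090
name: protein complementation assay
is_a: MI:0045 ! experimental interaction detection

[Term]
id: MI:0232
name: transcriptional complementation assay
is_a: MI:0090 ! protein complementation assay

[Term]
id: MI:0018
name: two hybrid
is_a: MI:0232 ! transcriptional complementation assay

[Term]
id: MI:0397
name: two hybrid array
is_a: MI:0018 ! two hybrid

[Term]
id: MI:0398
name: two hybrid pooling approach
is_a: MI:0018 ! two hybrid

[Term]
id: MI:0399
name: two hybrid fragment pooling approach
is_a: MI:0398 ! two hybrid pooling approach

[Term]
id: MI:0401
name: biochemical
is_a: MI:0045 ! experimental interaction detection

[Term]
id: MI:0091
name: chromatography technology
is_a: MI:0401 ! biochemical

[Term]
id: MI:0004
name: affinity chromatography technology
is_a: MI:0091 ! chromatography technology

[Term]
id: MI:0019
name: coimmunoprecipitation
is_a: MI:0004 ! affinity chromatography technology

[Term]
id: MI:0428
name: imaging technique
is_a: MI:0045 ! experimental interaction detection

[Term]
id: MI:0254
name: genetic interference
is_a: MI:0001 ! interaction detection method

[Term]
id: MI:0255
name: post transcriptional interference
is_a: MI:0001 ! interaction detection method

[Term]
id: MI:0063
name: interaction prediction
is_a: MI:0001 ! interaction detection method

[Term]
id: MI:0190
name: interaction type
is_a: MI:0000 ! molecular interaction

[Term]
id: MI:0208
name: genetic interaction
is_a: MI:0190 ! interaction type

[Term]
id: MI:0403
name: colocalization
is_a: MI:0190 ! interaction type

[Term]
id: MI:0914
name: association
is_a: MI:0190 ! interaction type

[Term]
id: MI:0915
name: physical association
is_a: MI:0914 ! association

[Term]
id: MI:0407
name: direct interaction
is_a: MI:0915 ! physical association
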