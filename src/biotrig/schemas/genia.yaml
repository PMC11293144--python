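name: genia
types:
- id: Gene_Expression
  label: Gene Expression
- id: Transcription
  label: Transcription
- id: Protein_Catabolism
  label: Protein Catabolism
- id: Phosphorylation
  label: Phosphorylation
- id: Localization
  label: Localization
- id: Binding
  label: Binding
- id: Regulation
  label: Regulation
- id: Positive_Regulation
  label: Positive Regulation
- id: Negative_Regulation
  label: Negative Regulation
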