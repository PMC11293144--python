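name: mlee
types:
- id: Cell_Proliferation
  label: Cell Proliferation
- id: Development
  label: Development
- id: Blood_Vessel_Development
  label: Blood Vessel Development
- id: Growth
  label: Growth
- id: Death
  label: Death
- id: Breakdown
  label: Breakdown
- id: Remodeling
  label: Remodeling
- id: Synthesis
  label: Synthesis
- id: Gene_Expression
  label: Gene Expression
- id: Transcription
  label: Transcription
- id: Catabolism
  label: Catabolism
- id: Phosphorylation
  label: Phosphorylation
- id: Dephosphorylation
  label: Dephosphorylation
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
- id: Planned_Process
  label: Planned Process
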