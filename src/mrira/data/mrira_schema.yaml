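# Default type registry for the medication-incident annotation scheme:
# 16 entity types, 11 event types, 5 event attributes, 6 argument roles and
# 9 relation types (10 endpoint constraints).
name: MRIRA
entity_types:
  general:
    - People
    - Location
    - Date/Time
    - Artefact
    - Knowledge
    - Function
  patient-specific:
    - Age group
    - Gender
  domain-specific:
    - Drug name
    - Drug form
    - Drug strength or amount
    - Drug dose
    - Drug frequency
    - Dose route
    - Dose duration
    - Medical condition
event_types:
  main:
    - Prescribing
    - Transcription
    - Dispensing
    - Administration
    - Monitoring
  supplementary:
    - Corrective action
    - Preventive action
    - Underlying and contributing factors
    - Error outcome
    - Action taken
    - Other action
attribute_names:
  - Action intended and actual
  - Action not intended but actual
  - Action intended but not actual
  - Action intent not clear
  - Negated
argument_roles:
  - Agent
  - Subject
  - Receiver
  - When
  - Where
  - For
relation_types:
  has dose:
    - [Drug name, Drug dose]
  has frequency:
    - [Drug dose, Drug frequency]
    - [Drug name, Drug frequency]
  has form:
    - [Drug name, Drug form]
  has route:
    - [Drug name, Dose route]
  has duration:
    - [Drug name, Dose duration]
  has strength or amount:
    - [Drug name, Drug strength or amount]
  has time:
    - [Drug dose, Date/Time]
  has:
    - [People, Medical condition]
  at:
    - [People, Location]
# Optional event-to-event discrepancy link; off by default and not counted
# among the nine entity relation types.
optional_link_types:
  Mismatch:
    enabled: false
# Variant labels seen in practice, mapped to their canonical spelling.
aliases:
  Dosage form: Drug form
  Strength or amount: Drug strength or amount
  Dose: Drug dose
  Frequency: Drug frequency
  Dose frequency: Drug frequency
  Route of administration: Dose route
  Duration: Dose duration
  Patient age: Age group
  Patient gender: Gender
  Date or time: Date/Time
  Underlying or contributing factor: Underlying and contributing factors
  Underlying contributing factor: Underlying and contributing factors
  Other actions: Other action
  Intended not actual: Action intended but not actual
  Error intended but not actual: Action intended but not actual
  Error not intended but actual: Action not intended but actual
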