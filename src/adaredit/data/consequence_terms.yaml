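# Sequence Ontology effect terms (SnpEff dialect) mapped to consequence flags.
# Edit or replace via the pipeline configuration to change what counts as a
# protein-coding or nonsense-mediated-decay consequence.
protein_coding:
  - missense_variant
  - synonymous_variant
  - stop_gained
  - stop_lost
  - stop_retained_variant
  - start_lost
  - initiator_codon_variant
  - coding_sequence_variant
  - frameshift_variant
  - inframe_insertion
  - inframe_deletion
  - disruptive_inframe_insertion
  - disruptive_inframe_deletion
  - protein_altering_variant
nmd:
  - NMD_transcript_variant
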