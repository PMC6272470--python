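# Default lectin family definitions and domain-token vocabulary.
#
# Accessions here are placeholders (LEC_* for lectin carbohydrate
# recognition domains, DOM_* for other protein domains): several lectin
# CRDs (EUL, Nictaba, CRA) have no Pfam identifier and are identified by
# alignment in practice, so a real analysis substitutes its own
# accession sets via a config file of this shape.  Reference domain
# lengths are typical full-length CRD sizes in amino acids; a hit
# shorter than truncation_fraction * reference_domain_length is flagged
# as a truncated domain.
#
# score_kind declares how score_or_evalue ranks competing lectin hits
# when a gene matches two families: "evalue" = lower is better,
# "bitscore" = higher is better.

score_kind: evalue

families:
  ABA:
    member_domain_accessions: [LEC_ABA]
    reference_domain_length: 140
    truncation_fraction: 0.75
  amaranthin:
    member_domain_accessions: [LEC_AMARANTHIN]
    reference_domain_length: 150
    truncation_fraction: 0.75
  CRA:
    member_domain_accessions: [LEC_CRA]
    reference_domain_length: 336
    truncation_fraction: 0.75
  cyanovirin:
    member_domain_accessions: [LEC_CYANOVIRIN]
    reference_domain_length: 100
    truncation_fraction: 0.75
  EUL:
    member_domain_accessions: [LEC_EUL]
    reference_domain_length: 150
    truncation_fraction: 0.75
  GNA:
    member_domain_accessions: [LEC_GNA]
    reference_domain_length: 110
    truncation_fraction: 0.75
  hevein:
    member_domain_accessions: [LEC_HEVEIN]
    reference_domain_length: 40
    truncation_fraction: 0.75
  jacalin:
    member_domain_accessions: [LEC_JACALIN]
    reference_domain_length: 130
    truncation_fraction: 0.75
  legume:
    member_domain_accessions: [LEC_LEGUME]
    reference_domain_length: 230
    truncation_fraction: 0.75
  LysM:
    member_domain_accessions: [LEC_LYSM]
    reference_domain_length: 45
    truncation_fraction: 0.75
  Nictaba:
    member_domain_accessions: [LEC_NICTABA]
    reference_domain_length: 165
    truncation_fraction: 0.75
  "ricin B":
    member_domain_accessions: [LEC_RICINB]
    reference_domain_length: 120
    truncation_fraction: 0.75

# Controlled vocabulary mapping non-lectin domain accessions to the
# token names used in canonical architecture strings.
token_vocabulary:
  DOM_KINASE: kinase
  DOM_SLG: S-locus
  DOM_PAN: PAN
  DOM_SRK: SRK
  DOM_TIR: TIR
  DOM_NBARC: NB-ARC
  DOM_LRR: LRR
  DOM_THAUMATIN: thaumatin
  DOM_BARWIN: Barwin
  DOM_GH5: GH5
  DOM_GH18: GH18
  DOM_GH19: chitinase
  DOM_GH27: GH27
  DOM_FBOX: F-box
  DOM_EEIG1: EEIG1/EHBP1
  DOM_RT: RT
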