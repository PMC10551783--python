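# Default relation-label → edge-class grouping for the synthetic vocabulary.
# Users override this file (or pass their own RelationClassMap) to bind a
# real 125-label vocabulary to the TREATS / AFFECTS / ASSOCIATED /
# DRUG_DRUG_ASSOC classes the drug-path patterns use.
may_treat: TREATS
may_be_treated_by: TREATS
affects: AFFECTS
affected_by: AFFECTS
associated_with: ASSOCIATED
gene_associated_with_disease: ASSOCIATED
disease_has_associated_gene: ASSOCIATED
chemical_associated_with_chemical: DRUG_DRUG_ASSOC
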