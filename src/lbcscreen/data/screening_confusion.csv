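cohort,tn,fp,fn,tp
full_agreement,255,25,3,17
clinical_balance,441,271,7,31
clinical_balance_reviewed,443,47,4,31
equal_balance,335,40,141,234
equal_balance_reviewed,335,29,45,234
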