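action	target	new_label	rationale	evidence
remove	<record_id of the divergent L. atricillus sequence>		outlier (6.3% from conspecifics), clusters within the L. aeneicollis clade; failed taxonomic validation	voucher_reexamination
remove	<record_id of the divergent L. salviae sequence>		outlier (17.2% from conspecifics), forms a singleton branch; failed taxonomic validation	voucher_reexamination
remove	<record_id of the divergent L. ochroleucus sequence>		outlier (15.2% from conspecifics), forms a singleton branch; failed taxonomic validation	voucher_reexamination
relabel	<record_id of a misdetermined L. ordinatus specimen>	Longitarsus juncicola	voucher morphology matches L. juncicola; repeat this row per re-determined specimen	voucher_reexamination
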