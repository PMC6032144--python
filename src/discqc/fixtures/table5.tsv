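origin	sample_id	LDB2	ADGRL4	EMCN	ANKRD29	OLFML2A	SPTLC3	ERFE	DSC3	DEFB1	ARAP2	CDKN2B
AF	4	-	-	NA	-	NA	NA	+	-	-	+	-
AF	10	+	+	NA	+	+	NA	-	-	+	+	-
AF	14	++	+	NA	+	++	NA	-	-	-	-	-
AF	17	-	-	-	-	-	+	-	++	+	+	+
AF	18	-	-	-	+	+	-	-	-	-	+	-
AF	20	+	+	+	+	+	-	-	-	+	-	-
AF	23	+	+	+	++	++	-	-	-	-	-	-
AF	25	++	+	+	+	++	-	-	-	-	-	-
NP	6	-	-	-	-	-	NA	-	-	-	+	-
NP	7	-	-	-	-	-	-	NA	NA	-	NA	-
NP	12	-	-	-	-	-	-	-	-	+	-	+
NP	19	-	-	-	-	NA	++	+	++	+	+	-
NP	20	NA	-	-	NA	-	+	+	-	+	-	-
NP	23	-	-	-	NA	-	-	NA	NA	-	NA	-
NP	24	-	NA	NA	-	-	-	-	+	+	-	-
NP	26	-	-	-	-	-	++	+	-	+	+	+
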