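individual_id	entheses	ovalization	fa_lesion	platymeric	vertebral	trauma	n_traits
032	+	?	+	+	+	-	4
034	+	?	+	+	-	-	3
064	+	+	+	+	+	+	6
081	+	?	?	+	+	-	3
082	+	?	+	+	-	-	3
092	-	?	+	?	+	+	3
103	+	?	+	?	-	+	3
116	+	?	?	+	+	+	4
118	+	+	+	+	+	-	5
130	+	?	+	+	?	-	3
135	+	?	+	-	+	-	3
148	+	-	+	-	+	-	3
153	+	+	+	-	+	+	5
161	+	+	-	+	+	-	4
164	+	?	+	-	+	-	3
166	+	?	?	+	?	+	3
170	+	?	+	+	?	?	3
174	+	?	+	+	?	-	3
177	+	?	+	+	?	-	3
186	+	?	+	+	?	?	3
198	?	-	+	?	+	+	3
209	+	+	+	-	+	+	5
213	+	+	+	+	+	-	5
215	+	+	-	+	+	-	4
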