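# Published midgut candidates that recur in cultured-cell datasets.
# overlap_degree = number of cultured-cell datasets (out of 4) in which the
# gene was also identified.
gene_id	direction	overlap_degree
AAEL012226	import_like	1
AAEL021771	import_like	1
AAEL019869	import_like	1
AAEL005013	import_like	1
AAEL006480	import_like	1
AAEL003619	import_like	1
AAEL000461	import_like	1
AAEL000417	import_like	1
AAEL011918	import_like	2
AAEL012440	import_like	3
AAEL001495	import_like	3
AAEL027424	export_like	1
AAEL028119	export_like	1
AAEL006855	export_like	1
AAEL012395	export_like	1
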