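# msicall reference profiles
# SYNTHETIC fixture: a hand-written stand-in profile for parser tests,
# not derived from any sequencing data.
schema_version: 1
profiles:
- locus: SYN-26
  n_source_reads: 1000
  pseudocount: 0.0
  mean: 25.85
  pmf: {24: 0.05, 25: 0.15, 26: 0.7, 27: 0.1}
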