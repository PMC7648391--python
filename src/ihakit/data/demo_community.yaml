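# Small demonstration community: three genomes spanning a 6:3:1 abundance
# range, one circular chromosome with a multi-copy plasmid, and ~10%
# cross-genome cassette divergence.
library:
  n_markers: 20
  marker_len: 300
genomes:
  - name: demo_a
    length: 80000
    gc_fraction: 0.40
    circular: true
    abundance_weight: 0.6
    plasmids: [[12000, 2]]
    cassette_divergence: 0.10
  - name: demo_b
    length: 60000
    gc_fraction: 0.55
    abundance_weight: 0.3
    cassette_divergence: 0.10
  - name: demo_c
    length: 40000
    gc_fraction: 0.68
    circular: true
    abundance_weight: 0.1
    cassette_divergence: 0.10
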