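# Full-pipeline config for `chromolens run-all --config examples/run_all.yaml`.
# Generate the inputs first:  chromolens simulate cohort --seed 42 --out demo
inputs:
  segments: demo/segments.tsv
  samples: demo/samples.tsv
summarize:
  unit: sample            # or: patient
dedupe:
  reciprocal_overlap: 0.9
tally:
  exclude: []             # sample ids with complex events to drop from the tally
cdr:
  kind: DEL
  min_support: 2
associations:
  - name: progression
    group_a: [post-PV AML, post-ET AML, post-PMF AML]
    group_b: [Polycythemia vera, post-PV MF, Essential thrombocythemia,
              post-ET MF, Primary Myelofibrosis, post-PMF AP]
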