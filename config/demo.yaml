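# Demo pipeline configuration: synthetic study-scale region.
seed: 42
simulate: true
n_sites: 702
n_nodes: 1500
sampler_n: 10000
thresholds: [30.0, 40.0]
density_cutpoints: [100.0, 1000.0]
fertility_cutpoints: [1.3, 1.6]
scenarios:
  - name: all
    require_pediatrics: false
    min_live_births: null
  - name: pediatrics_only
    require_pediatrics: true
    min_live_births: null
  - name: min600
    require_pediatrics: false
    min_live_births: 600
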