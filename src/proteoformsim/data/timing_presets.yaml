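# Workflow timing presets. Durations are wall-clock hours for one complete
# comparative study; hands_on_fraction is the share of each step needing an
# operator at the bench. entities = proteins/proteoforms both quantified and
# identified by the workflow, the denominator of per-entity throughput.
#
# "du145-2023": a full 2D-DIGE vs label-free shotgun comparison of DU145
# prostate-carcinoma lysates (6 technical + 3 biological replicates; 144 spots
# picked and identified on the gel side, 703 canonical proteins on the shotgun
# side). Roughly half the gel workflow and a tenth of the shotgun workflow is
# hands-on.
du145-2023:
  dige:
    entities: 144
    steps:
      - name: gel_runs_and_image_analysis
        hours: 183.0
        hands_on_fraction: 0.5
      - name: spot_digestion_and_ms_identification
        hours: 144.0
        hands_on_fraction: 0.5
  shotgun:
    entities: 703
    steps:
      - name: sample_prep_and_digestion
        hours: 7.7
        hands_on_fraction: 1.0
      - name: lc_ms_runs_and_data_analysis
        hours: 69.3
        hands_on_fraction: 0.0
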