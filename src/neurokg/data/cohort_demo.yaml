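# Cohort-selection conservation preset: plants exactly 78 sub-threshold
# (MoCA < 26) subjects in dataset1 and 32 in dataset2, 110 total, so the
# knowledge-graph cohort query has a known planted answer. dataset1 is
# larger than in the table1 preset because 78 sub-threshold subjects cannot
# fit in a 50-subject source.
seed: 0
planted_effect_delta: 0.8
volumes:
  volume_mean_mm3: 3700.0
  volume_sd_mm3: 350.0
  icv_mean_mm3: 1480000.0
  icv_sd_mm3: 130000.0
sources:
  - name: dataset1
    dialect: verbose
    id_prefix: "S1-"
    id_start: 1001
    groups:
      PD:
        n: 100
        n_below: 70
        female_fraction: 0.28
        age_mean: 67.1
        age_sd: 8.0
        education_mean: 17.9
        education_sd: 2.5
        hy_mean: 2.29
        hy_sd: 0.6
        moca_mean: 25.0
        moca_sd: 3.0
      HC:
        n: 30
        n_below: 8
        female_fraction: 0.62
        age_mean: 69.7
        age_sd: 8.0
        education_mean: 17.1
        education_sd: 2.5
        hy_mean: 0.0
        hy_sd: 0.0
        moca_mean: 26.6
        moca_sd: 2.5
  - name: dataset2
    dialect: terse
    id_prefix: ""
    id_start: 3001
    groups:
      PD:
        n: 69
        n_below: 28
        female_fraction: 0.34
        age_mean: 61.8
        age_sd: 9.0
        education_mean: 16.4
        education_sd: 2.5
        hy_mean: 1.65
        hy_sd: 0.5
        moca_mean: 26.9
        moca_sd: 2.5
      HC:
        n: 31
        n_below: 4
        female_fraction: 0.39
        age_mean: 58.7
        age_sd: 9.0
        education_mean: 17.2
        education_sd: 2.5
        hy_mean: 0.0
        hy_sd: 0.0
        moca_mean: 28.1
        moca_sd: 2.0
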