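# Cohort preset calibrated to the published per-group demographic margins:
# group sizes, % female, mean age, mean education, mean Hoehn & Yahr stage,
# and mean MoCA total per source and group. Standard deviations and the
# volume/ICV priors are package defaults (the source tables publish means
# only); see docs/methods.md.
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
        n: 29
        female_fraction: 0.28
        age_mean: 67.1
        age_sd: 8.0
        education_mean: 17.9
        education_sd: 2.5
        hy_mean: 2.29
        hy_sd: 0.6
        moca_mean: 25.0
        moca_sd: 3.0
        fluency_mean: 18.0
        fluency_sd: 5.0
      HC:
        n: 21
        female_fraction: 0.62
        age_mean: 69.7
        age_sd: 8.0
        education_mean: 17.1
        education_sd: 2.5
        hy_mean: 0.0
        hy_sd: 0.0
        moca_mean: 26.6
        moca_sd: 2.5
        fluency_mean: 21.0
        fluency_sd: 5.0
  - name: dataset2
    dialect: terse
    id_prefix: ""
    id_start: 3001
    groups:
      PD:
        n: 69
        female_fraction: 0.34
        age_mean: 61.8
        age_sd: 9.0
        education_mean: 16.4
        education_sd: 2.5
        hy_mean: 1.65
        hy_sd: 0.5
        moca_mean: 26.9
        moca_sd: 2.5
        fluency_mean: 19.0
        fluency_sd: 5.0
      HC:
        n: 31
        female_fraction: 0.39
        age_mean: 58.7
        age_sd: 9.0
        education_mean: 17.2
        education_sd: 2.5
        hy_mean: 0.0
        hy_sd: 0.0
        moca_mean: 28.1
        moca_sd: 2.0
        fluency_mean: 22.0
        fluency_sd: 5.0
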