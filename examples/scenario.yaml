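# Example registry scenario for `hpbbench simulate --config examples/scenario.yaml`.
#
# Two hospitals over two registration years.  Per procedure group each
# hospital specifies its annual volume, the generative event probabilities
# and a length-of-stay model (negative binomial, given as median days and a
# dispersion size).  Death is drawn conditionally on a severe
# (Clavien-Dindo >= 3a) complication: p_death_given_severe is the
# failure-to-rescue probability.  Liver groups (MINOR_LR, MAJOR_LR) need
# p_margin_adequate; pancreas groups (PD, DP) need p_popf_bc and
# p_reoperation.
label: two-hospital-demo
seed: 42          # overridden by --seed on the command line
years: [2020, 2021]
hospitals:
  - hospital_id: A
    procedures:
      MINOR_LR:
        volume: 60                      # resections per year
        p_severe: 0.098                 # Clavien-Dindo >= 3a
        p_death_given_severe: 0.054     # failure to rescue
        p_death_given_not_severe: 0.0008
        p_readmission: 0.08
        p_margin_adequate: 0.96
        los_median: 5
        los_dispersion: 4.0
      PD:
        volume: 40
        p_severe: 0.36
        p_death_given_severe: 0.075
        p_death_given_not_severe: 0.0
        p_readmission: 0.12
        p_popf_bc: 0.12
        p_reoperation: 0.05
        los_median: 10
        los_dispersion: 4.0
  - hospital_id: B
    procedures:
      MINOR_LR:
        volume: 25
        p_severe: 0.098
        p_death_given_severe: 0.054
        p_death_given_not_severe: 0.0008
        p_readmission: 0.08
        p_margin_adequate: 0.96
        los_median: 5
        los_dispersion: 4.0
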