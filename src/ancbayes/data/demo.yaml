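# Scaled-down demonstration run: 4 survey waves of 100 clusters x 10
# households, every sampled woman eligible, completing on one CPU in a few
# minutes.  Generating odds ratios for pregnancy intention match the
# published adjusted estimates for the ">=1 skilled visit" outcome
# (mistimed aOR 0.59 => log-odds -0.527; unwanted aOR 0.67 => -0.400).
seed: 20140
out: runs/demo
simulate:
  years: [2004, 2007, 2011, 2014]
  n_clusters: 100
  households_per_cluster: 10
  sigma_u: 0.5
  p_recent_birth: 1.0
  p_missing_intention: 0.0
  beta:
    Intercept: 0.45
    "intention[mistimed]": -0.527
    "intention[unwanted]": -0.400
    "education[primary]": 0.25
    "education[secondary]": 0.45
    "education[higher]": 0.60
    "wealth_quintile[poorer]": 0.15
    "wealth_quintile[middle]": 0.25
    "wealth_quintile[richer]": 0.35
    "wealth_quintile[richest]": 0.55
    "residence[rural]": -0.35
model:
  terms: [intention, education, wealth_quintile, residence, community_poverty, community_anc4]
  outcomes: [y_any, y_four]
screening:
  threshold: 0.20
mcmc:
  n_chains: 3
  n_burnin: 600
  n_kept: 1500
historical_mcmc:
  n_chains: 2
  n_burnin: 300
  n_kept: 800
diagnostics:
  run: true
  run_mcmc: false
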