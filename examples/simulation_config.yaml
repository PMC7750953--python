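# Study conditions for `puma simulate --config examples/simulation_config.yaml --out sim/`
# Any omitted field keeps its default (shown here explicitly).
m: 20              # regulators (all flagged as miRNAs)
n: 60              # genes
tissues: 4
samples: 100       # expression samples per tissue
density: 0.05      # Bernoulli rate of background prior edges
discordance: 0.3   # fraction of prior cells resampled between priors A and B
beta: 2.0          # latent-factor loading of planted modules
sigma: 1.0         # i.i.d. expression noise sd
prior_dropout: 0.3 # fraction of planted edges withheld from the prior
seed: 1
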