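# Maintenance experiment: EARLY-SPOV vs MFCL, poor environment,
# spillover allele recessive, juvenile survival 0.7.
# Run:  spovsim simulate --config examples/maintenance_poor_recessive.yaml \
#           --seed 42 --out runs/maintenance_poor
environment: poor
strategy_pair: [EARLY-SPOV, MFCL]
dominance: mfcl
different: 0.7
initial_state: maintenance
max_generations: 2000
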