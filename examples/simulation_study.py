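"""A reduced run of the simulation study comparing recovery performance.

Runs the {MCAR, MAR} x {5%, 10%, 15%, 20%} scenario grid at a reduced
replication count and prints validity (fraction of replicates whose
learned structure matches the generating one up to Markov equivalence),
the logistic-comparator validity, and per-mechanism robustness (the
standard deviation of validity across missing rates).

At the full 10,000 replicates per scenario the validity columns settle
near 0.97 (MCAR) and 0.93-0.98 (MAR); 200 replicates per scenario keep
this script under a couple of minutes while showing the same pattern.
"""

from bnmmi import default_scenarios, run_experiment

REPS = 200

specs = default_scenarios(reps=REPS, n=2000, master_seed=1)
table = run_experiment(specs, logistic=True)

print(f"{'mechanism':<10}{'rate':>6}{'validity':>10}{'logistic':>10}")
for s in table.scenarios:
    print(
        f"{s.spec.mechanism:<10}{s.spec.missing_rate:>6.2f}"
        f"{s.validity:>10.3f}{s.logistic_validity:>10.3f}"
    )

for mech in ("MCAR", "MAR"):
    print(f"robustness {mech}: sd = {table.robustness(mech, 'sd'):.4f}")

# validity ~0.97 across MCAR rates and >=0.93 across MAR rates means the
# learned structure almost always equals the generating one; a smaller
# robustness value means validity barely moves with the missing rate.
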