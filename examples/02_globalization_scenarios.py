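"""Compare the eight globalization scenarios.

Each of learning, contact, and environment is either local (ring neighbours)
or global (whole population).  With w < 0, any globalization lowers the
average level of cognitive control; global environment preserves strategic
diversity and communities while local environment homogenizes; global
learning destroys communities.  Reduced scale (2e4 generations, 3
replicates) so the script finishes in about a minute.
"""

from cogcontrol import RunConfig, Scenario, run_replicates, summarize_replicates

print(f"{'learning':>9} {'contact':>9} {'environ':>9}   <x>     a      var(x)")
for idx, scenario in enumerate(Scenario.all_scenarios()):
    config = RunConfig(scenario=scenario, generations=20_000,
                       seed=1000 * idx + 1)
    s = summarize_replicates(run_replicates(config, 3))
    print(f"{scenario.learning:>9} {scenario.contact:>9} {scenario.environment:>9}"
          f"   {s.mean_control:.3f}  {s.assortment:+.3f}  {s.strategy_variance:.4f}")

# The fully local row keeps the most control; rows with a global environment
# have high variance (coexisting automatic and controlled agents); only
# local-learning rows show assortment a > 0 (communities on the ring).
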