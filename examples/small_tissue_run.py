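"""A short full-model 2D run: mutation-driven tumor initiation.

Packs a 40-um disc with epithelial cells, runs 300 s of the complete model
(pressure-modulated cycle and death, mutation at mitosis, immune response
at defaults) and prints the counts trajectory.  At the default parameters
the pressure-coupled death multiplier G(0) = 4.5 keeps every lineage
subcritical, so expect the tissue to thin rather than a tumor to take over
— see docs/methods.md for why, and the immune comparison example for a
scenario with a viable tumor.
"""

from tumorinit import run
from tumorinit.experiments import demo_config

cfg = demo_config(dim=2, seed=42)
result = run(cfg)

print(result.counts.tail(8).to_string(index=False))
m = result.meta
print(f"\nstopped: {m['stopped']} at t={m['final_t']:.0f} s; "
      f"divisions={m['cum_divisions']}, mutations={m['cum_mutations']}, "
      f"deaths={m['cum_deaths']}, intravasated={m['cum_intravasations']}")
print("Columns: time, live counts per phenotype, tumor fraction of all "
      "live cells, cumulative tumor cells lost to vessels.")
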