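"""Interfacial partitioning free energy of the ENTH H0 helix.

Sweeps the helical fraction of MSTSSLRRQMKNIVH (charged N-terminus,
amidated C-terminus) and prints the water -> bilayer-interface transfer
free energy.  Folding the helix at the interface is what makes
partitioning favourable.
"""

from enthcg.partitioning import H0_SEQUENCE, helicity_sweep

sweep = helicity_sweep(H0_SEQUENCE, helicities=[0.0, 0.5, 0.85, 1.0])
print(sweep.to_string(index=False, float_format="%.2f"))
row85 = sweep[sweep.helicity == 0.85].iloc[0]
row100 = sweep[sweep.helicity == 1.0].iloc[0]
print(f"\n85% helix: {row85.dg_total:.1f} kcal/mol; "
      f"100% helix: {row100.dg_total:.1f} kcal/mol "
      "(favourable only once helical)")
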