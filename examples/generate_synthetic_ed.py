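"""Generate a synthetic ED cohort and inspect its calibrated structure.

Builds one study's worth of encounters (13-week horizon split into pre /
educational / post periods) plus the minute-level ED census series, then
prints the marginal moments the generator is calibrated to: acuity mix,
age, right-skewed length of stay, procedure frequencies, and how often the
department is saturated.
"""

from vppflow import GeneratorConfig, generate_ed_state_series, generate_encounters

cfg = GeneratorConfig(n_encounters=13_700, seed=1)
enc = generate_encounters(cfg)

print(f"encounters: {len(enc)}  periods: {enc['period'].value_counts().to_dict()}")
print(f"ESI mean (SD):  {enc['esi'].mean():.2f} ({enc['esi'].std():.2f})")
print(f"age mean (SD):  {enc['age'].mean():.1f} ({enc['age'].std():.1f})")
print(f"LOS mean (SD):  {enc['los'].mean():.1f} ({enc['los'].std():.1f}) min, "
      f"skew {enc['los'].skew():.2f}")
procs = {c: f"{100 * enc[c].mean():.1f}%" for c in
         ("proc_iv", "proc_ct_con", "proc_ct_noncon", "proc_xray", "proc_us")}
print(f"procedures: {procs}")
print(f"true bed-need prevalence: {enc['true_bed_need'].mean():.3f} "
      "(always true for ESI 1-2, declining with acuity)")

states = generate_ed_state_series(cfg, horizon_minutes=30 * 1440)
print(f"\nED-state series: {len(states)} ten-minute steps over 30 days")
print(f"saturated fraction of minutes: {states['saturated'].mean():.3f} "
      "(surge days push the census past the institutional threshold)")
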