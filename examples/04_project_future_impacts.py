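"""Project heat-attributable mortality to 2100 under two emission pathways.

Builds a small climate-scenario ensemble (two models x two pathways) around
the observed climatology, bias-corrects it with the month-wise
trend-preserving correction, replicates the observed seasonal death profile
into the future (demographics held fixed), and projects the relative excess
mortality per 20-year period with pooled coefficient x member eCIs.
"""

import pandas as pd

import heatmort as hm

cfg = hm.SynthConfig(n_units=10, year_start=1981, year_end=2015, seed=4)
panel = hm.generate_panel(cfg)
full = hm.generate_panel(cfg, keep="all")
model = hm.fit_heat_model(panel)

members = []
for model_id, bias in (("rcmA", 1.2), ("rcmB", -0.8)):
    for pathway, warming in (("rcp45", 0.15), ("rcp85", 0.45)):
        sc = hm.ScenarioConfig(model_id=model_id, pathway_id=pathway,
                               bias_mean=bias, bias_scale=1.3,
                               warming_per_decade=warming,
                               year_start=1981, year_end=2100, seed=4)
        raw = hm.generate_scenario(sc, full)
        params = hm.fit_correction(full, raw, range(1981, 2016))
        members.append(hm.apply_correction(raw, params))

baseline = hm.baseline_death_series(panel, range(1981, 2101))
res = hm.project_impacts(members, model.reduced, model.mmt.mmt, baseline,
                         n_sim=500, seed=4)
print("ensemble-mean relative excess mortality (%) by 20-year period:")
print(res.summary.assign(
    period=lambda d: d.period_start.astype(str) + "-" + d.period_end.astype(str)
).pivot(index="period", columns="pathway", values="af_total_pct").round(2))
end = res.summary[res.summary.period_start == 2081].set_index("pathway")
print(f"\nby 2081-2100 the high-emission pathway roughly "
      f"{end.loc['rcp85', 'af_total_pct'] / end.loc['rcp45', 'af_total_pct']:.1f}x "
      "the mitigation pathway; the gap opens after mid-century because both "
      "share the historical climate and diverge only through the trend.")
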