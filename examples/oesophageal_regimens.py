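"""Ranking three oesophageal-cancer chemoradiotherapy regimens in silico.

Herskovic (chemo weeks 1/5/8/11, 25 x 2 Gy weeks 1-5), modified
Herskovic (chemo weeks 1/3/6/10, radiation weeks 6-10) and an
experimental plan (chemo weeks 1/3/6/9, 20 x 2.5 Gy weeks 12-15) are
simulated over 17 weeks from the same grown tumour.  Each chemo cycle
is a cisplatin-like G1-specific bolus on day 1 plus daily
5-FU-like S-G2-M-specific doses on days 1-4.

Treatment efficacy is compared by total cell kill; the small 2 x 2 mm
patch regrows to confluence between/after courses, so final counts
saturate while cumulative kill still separates the regimens.

Runtime: a few minutes per regimen.
"""

import tumourca as tca

cfg = tca.default_config()
grown = tca.run_experiment(cfg, None, seed=1, horizon_h=400.0)
horizon = 400.0 + 17 * 168.0  # 17 treatment weeks after the growth phase

print("regimen               total kill   (radiation + chemo)   final")
for preset in ("herskovic", "modified_herskovic", "experimental"):
    res = tca.run_experiment(cfg, tca.build_schedule(preset), seed=1,
                             horizon_h=horizon, from_world=grown.world,
                             keep_world=False)
    last = res.census.iloc[-1]
    rad, chem = int(last.killed_radiation_cum), int(last.killed_chemo_cum)
    print(f"{preset:20s} {rad + chem:10d}   ({rad:5d} + {chem:5d})"
          f" {res.final_count:7d}")

print()
print("Expected: experimental > modified Herskovic > Herskovic in total")
print("kill, i.e. the experimental plan controls the tumour best and the")
print("original Herskovic plan worst.")
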