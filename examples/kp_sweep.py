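"""Sensitivity of auxin distribution to the flux-feedback weight kP.

Sweeps the auxin-flow contribution to PIN sensitivity.  At kP = 0 the
polarization loses its flux feedback and inner ground tissues are starved
of auxin; large kP strengthens the reflux loop and piles auxin up in the
recirculation region.
"""

from rootsim import ScenarioConfig, sweep
from rootsim.template import TemplateConfig

cfg = ScenarioConfig(steps=1200, seed=3, record_every=300,
                     template=TemplateConfig(cells_per_file=4))
results = sweep(cfg, "polarity.kP", [0.0, 3.0])

for kp, tables in results.items():
    prof = tables["profile"]
    ts = tables["timeseries"]
    print(f"kP = {kp:g}: mean cell auxin {ts.mean_cell_auxin.iloc[-1]:.2f} nM, "
          f"max profile bin {prof.auxin_mean.max():.2f} nM")
# Compare the two profiles: the kP = 0 run distributes visibly less auxin
# into the tissues below the source.
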