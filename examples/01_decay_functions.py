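"""Distance-decay families and their effective catchments.

Evaluates the three decay forms used by the prediction methods at a few
travel times and reports each family's effective catchment — the travel
time beyond which the decay weight drops below 0.01.
"""

from fcavisits import DecaySpec, effective_catchment

families = {
    "logistic (iFCA, mu=60, s=6)": DecaySpec.logistic(mu=60, s=6),
    "log-logistic (M2SFCA, a=13.39, b=1.89)": DecaySpec.log_logistic(),
    "gaussian zonal (E2SFCA, 30/60/90/120)": DecaySpec.gaussian_zonal(),
}

print(f"{'travel time (min)':>38}: " + "".join(f"{d:>8}" for d in (0, 15, 30, 60, 90, 119)))
for name, spec in families.items():
    weights = "".join(f"{spec.weight(float(d)):8.3f}" for d in (0, 15, 30, 60, 90, 119))
    print(f"{name:>38}: {weights}")

print()
for name, spec in families.items():
    ec = effective_catchment(spec, threshold=0.01, max_min=120.0)
    capped = " (never drops below 0.01 inside the 120-min catchment)" if ec.capped else ""
    print(f"effective catchment, {name}: {ec.minutes:.1f} min{capped}")

# The weight is the fraction of a location's demand a hospital at that
# travel time can still attract; the effective catchment tells how far a
# hospital's influence reaches before it becomes negligible.
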