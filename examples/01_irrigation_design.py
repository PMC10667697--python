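"""Deficit-irrigation design: net and gross depths for a two-layer root zone.

The net depth is the soil-water deficit (field capacity minus current
content, times thickness, summed over layers); dividing by the 90%
application efficiency gives the gross depth, of which the drought
treatment receives half.
"""

from trialqg import SoilLayer, irrigation_plan, net_irrigation_depth

layers = [
    SoilLayer(theta_fc=0.32, theta=0.22, dz=0.30),  # 0-30 cm
    SoilLayer(theta_fc=0.33, theta=0.23, dz=0.30),  # 30-60 cm
]

d_n = net_irrigation_depth(layers)
control, deficit = irrigation_plan(layers, efficiency=0.9, treatment_fractions=(1.0, 0.5))

print(f"net irrigation depth          : {d_n * 1000:.1f} mm")
print(f"gross depth (90% efficiency)  : {control.d_g * 1000:.1f} mm")
print(f"applied, well-watered control : {control.applied_depth * 1000:.1f} mm")
print(f"applied, 50% deficit (drought): {deficit.applied_depth * 1000:.1f} mm")
# The control replaces the full deficit plus conveyance losses; the drought
# treatment applies exactly half of that gross amount.
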