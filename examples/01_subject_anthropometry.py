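"""From anthropometrics to the cellular scale.

Builds the subject of the 42-day overfeeding study and prints the derived
quantities that initialise a simulation: BMI, the mean visceral adipocyte
diameter implied by it, the body-composition split, and the critical cell
volume beyond which an adipocyte turns proinflammatory.
"""

from adipoflame import (
    SubjectProfile,
    adipocyte_diameter,
    bmi,
    critical_volume,
    fat_mass,
    free_fat_mass,
    sphere_volume,
)

subject = SubjectProfile(body_weight_0=73.7, height=1.75, age=36, gender="male")
b = bmi(subject)
d = adipocyte_diameter(b, subject.gender)

print(f"BMI:                      {b:.2f} kg/m^2")
print(f"mean adipocyte diameter:  {d:.2f} um")
print(f"mean adipocyte volume:    {sphere_volume(d):.3e} uL")
print(f"critical volume v_c:      {critical_volume(subject.gender):.3e} uL")
print(f"fat-free mass:            {free_fat_mass(subject):.2f} kg")
print(f"fat mass:                 {fat_mass(subject):.2f} kg")
print()
print("The fat mass is the reservoir the diet fills: simulated tissue-volume")
print("growth is converted back to body weight in proportion to FM/(1-delta).")
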