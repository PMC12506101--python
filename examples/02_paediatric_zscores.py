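"""Paediatric BMI categorisation with the LMS growth-reference transform.

For a child, "obese" is not a fixed BMI: it depends on sex and age.  The LMS
method turns a BMI x into a z-score via z = ((x/M)^L - 1)/(L*S) using the
age- and sex-specific Box-Cox power (L), median (M) and coefficient of
variation (S); categories are assigned at percentile thresholds (defaults
2nd / 85th / 95th).
"""

from bmirrda.config import StudyConfig
from bmirrda.derive import categorise_cyp, lms_zscore, reference_lookup
from bmirrda.synth import generate_reference

config = StudyConfig()
reference = generate_reference()  # synthetic L,M,S curves, ages 24-228 months

print("BMI 21 kg/m2 means different things at different ages (girl):")
for age_months in (36, 84, 132, 180, 225):
    L, M, S = reference_lookup(reference, "F", age_months)
    z = lms_zscore(21.0, L, M, S)
    cat = categorise_cyp(z, config.cyp_z_thresholds())
    print(f"  age {age_months:3d} m: median M={M:5.2f}  z={z:+5.2f}  -> {cat}")
# At age 3 a BMI of 21 is far above the median (obese); by the late teens the
# same value is close to the median (normal weight).

zu, zo, zb = config.cyp_z_thresholds()
print(f"\nz thresholds: underweight < {zu:.3f}, overweight >= {zo:.3f}, obese >= {zb:.3f}")
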