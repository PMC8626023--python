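"""Score colon damage for single animals against a control reference.

The macroscopic total (0-15) adds stool consistency (0-3), ulcers (0-3),
percent-change points for colon length and weight (0-4 each, relative to
the control-group means) and fecal blood (0/1).
"""

from types import SimpleNamespace

from colitistats import ControlReference, macroscopic_total, microscopic_total
from colitistats import HistologySubscores

ref = ControlReference(control_mean_length=10.0, control_mean_weight=0.25)

healthy = SimpleNamespace(stool_score=0, ulcer_score=0, fecal_blood=0,
                          colon_length=10.0, colon_weight=0.25)
sick = SimpleNamespace(stool_score=3, ulcer_score=2, fecal_blood=1,
                       colon_length=8.0, colon_weight=0.275)

for name, animal in (("healthy", healthy), ("colitic", sick)):
    res = macroscopic_total(animal, ref)
    print(f"{name}: stool {res.stool_points} + ulcers {res.ulcer_points} "
          f"+ length {res.length_points} + weight {res.weight_points} "
          f"+ blood {res.blood_points} = total {res.total}")

histo = HistologySubscores(goblet_depletion=1, crypt_abscesses=0,
                           mucosal_architecture=2, muscle_thickening=1,
                           immune_infiltration=2)
print(f"microscopic total (3 = normal tissue .. 11 = worst): "
      f"{microscopic_total(histo)}")
print("\nThe colitic animal's 20% colon shortening scores 2 points and its"
      "\n10% weight change 1 point; a total of 0 means no inflammation.")
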