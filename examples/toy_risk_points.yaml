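# TOY risk-point table for tests and demos only.
# The additive risk model requires a published point table supplied by the
# user; no clinically validated defaults ship with the package. Points
# here are illustrative (1 point per adverse level, age banded by decade).
points:
  age:            # ascending [lower_bound, points] bands
    - [40, 1]
    - [50, 2]
    - [60, 3]
    - [70, 4]
  sex: {M: 1, F: 0}
  symptom_type: {typical: 2, atypical: 1, noncardiac: 0}
  diabetes: {1: 1, 0: 0}
  hypertension: {1: 1, 0: 0}
  family_history: {1: 1, 0: 0}
  smoking: {1: 1, 0: 0}
cutpoints: [3, 6]
classes: [low, intermediate, high]
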