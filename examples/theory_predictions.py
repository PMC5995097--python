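"""Print the theoretical exponent predictions the empirical fits are judged against.

Flow Similarity gives, for each variable pair, a range of exponents
between the hydraulic (flow, alpha_F = 2) and biomechanical (elastic,
alpha_F = 2/3) endpoints; WBE gives single points, anchored by the
mass ~ diameter^(8/3) law.
"""

from fractions import Fraction

from allomtree import fs_exponent, prediction_table

df = prediction_table()
print(df[["model", "y", "x", "flow", "elastic", "point", "reconstructed"]]
      .to_string(index=False))

# the FS expressions can be evaluated at any alpha_F, not just the endpoints
alpha = Fraction(4, 3)
print(f"\nAt an intermediate alpha_F = {alpha}, surface area ~ volume scales "
      f"with exponent {fs_exponent(('surface_area', 'volume'), alpha)} "
      "(between the flow value 3/4 and elastic value 5/8).")
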