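"""Evidence quality, data deficiency and error bars.

The data-uncertainty index U is the mean evidence-grade weight over scored
slots (high 0, medium 0.5, low 1) plus the fraction of data-deficient
slots.  Drawn as a symmetric error bar, it shows when a score could cross
a category boundary: Josephine scores as a likely EBSA, but its error bar
dips into the low-likelihood half.
"""

from seamount_ebsa import (
    data_deficiency,
    ebsa_score,
    error_bounds,
    fixture,
    uncertainty_index,
)

rec = fixture("Josephine")
res = ebsa_score(rec)
u = uncertainty_index(rec, "ebsa")
lo, hi = error_bounds(res.score, u)

print(f"Josephine EBSA score:    {res.score_2dp:.2f} ({res.category})")
print(f"  mean grade weight:     {u.dq_mean:.2f}")
print(f"  data deficiency:       {data_deficiency(rec, 'ebsa'):.2f} "
      f"(share of the 10 indicator slots)")
print(f"  uncertainty index U:   {u.u_2dp:.2f}")
print(f"  error interval:        {lo:.2f} .. {hi:.2f}")
print()
print("The interval spans the low/high boundary at 3: with better survey "
      "data Josephine could resolve to either category, flagging it as a "
      "research priority.")
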