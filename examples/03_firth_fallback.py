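"""Firth-fallback logistic regression under separation.

A rare exposure that appears only in cases sends the ordinary logistic
estimate to infinity; the Firth penalty (Jeffreys prior) keeps it finite.
The second half measures empirical type-I error under a rare-variant,
case-control-imbalanced null, where the fallback keeps the size near the
nominal level.
"""

import numpy as np
import pandas as pd

from phewaskit.association import (
    build_design, fit_logistic, firth_fallback, simulate_type1,
)

# 2x2 with two empty cells: 2 exposed cases, 2 unexposed controls
x = np.r_[1.0, 1.0, 0.0, 0.0]
y = np.r_[1.0, 1.0, 0.0, 0.0]
design = build_design(pd.Series(y), pd.DataFrame({"x": x}), binary=True)

plain = fit_logistic(design)
print(f"plain logistic: converged={plain.converged} ({plain.reason})")

fb = firth_fallback(design)
print(f"firth fallback: method={fb.method}, beta={fb.beta[0]:.4f}, "
      f"se={fb.se[0]:.4f}")
print(f"closed form for this table: log((2.5*2.5)/(0.5*0.5)) = "
      f"{np.log(25.0):.4f}")
print()

std, fall = simulate_type1(n=5000, case_fraction=0.02, maf=0.05,
                           alpha=0.05, reps=200, seed=7)
print(f"type-I error at alpha=0.05 over 200 null replicates "
      f"(n=5000, 2% cases, maf 0.05):")
print(f"  standard Wald logistic: {std:.3f}")
print(f"  firth fallback:         {fall:.3f}")
print("Both should sit near 0.05; the fallback must never exceed the")
print("standard test, and it keeps every estimate finite.")
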