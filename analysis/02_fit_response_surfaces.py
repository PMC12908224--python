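"""Fit quadratic response-surface models to both packaged DOE tables.

First DOE: fits the ten-term reduced model (the term set found significant
in the study) per response, verifies that per-response significance
screening unioned across responses reproduces that exact set, and
evaluates the models at the reported optimum (w=100 µm, t=100 µm, NS=16,
LA=0.8 mm, SA=0.5 mm).

Second DOE: per-response t-screened reduced models over (w, t, SA),
evaluated at the reported refined optimum (w=70 µm, t=140 µm, SA=0.5 mm).

Writes coefficient tables, R², diagnostics and the predictions under
results/.
"""

import json
from pathlib import Path

import pandas as pd

from stentopt import RESPONSES, StentDesign, eq5_terms, fit, load_table4, load_table5
from stentopt.design_space import DOE2_FIXED
from stentopt.rsm import reduce_model, residual_diagnostics, screen_union

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

DOE1_OPTIMUM = StentDesign(w=100, t=100, NS=16, LA=0.8, SA=0.5)
DOE2_OPTIMUM = StentDesign(w=70, t=140, SA=0.5, **DOE2_FIXED)


def main() -> None:
    t4, t5 = load_table4(), load_table5()

    union = screen_union(t4)
    same = [t.label for t in union] == [t.label for t in eq5_terms()]
    print(f"DOE1 union of screened terms == printed reduced set: {same}")

    rows, preds = [], {}
    for m in RESPONSES:
        model = fit(t4, m.key, eq5_terms(), units="natural")
        diag = residual_diagnostics(model)
        coef = model.coefficients()
        coef.insert(0, "response", m.key)
        rows.append(coef)
        preds[m.key] = model.predict(DOE1_OPTIMUM)
        print(f"DOE1 {m.label}: R²={model.r_squared:.4f}, "
              f"prediction at optimum = {preds[m.key]:.3f} {m.unit}, "
              f"Shapiro-Wilk p={diag.shapiro_p:.3f}")
        model.to_json(OUT / f"model_doe1_{m.key}.json")
    pd.concat(rows).to_csv(OUT / "coefficients_doe1.csv", index=False)
    json.dump({k: round(v, 4) for k, v in preds.items()},
              open(OUT / "predictions_doe1_optimum.json", "w"), indent=1)

    rows, preds = [], {}
    for m in RESPONSES:
        model, diag = reduce_model(t5, m.key)
        labels = [t.label for t in model.terms if t.kind != "intercept"]
        coef = model.coefficients()
        coef.insert(0, "response", m.key)
        rows.append(coef)
        preds[m.key] = model.predict(DOE2_OPTIMUM)
        print(f"DOE2 {m.label}: kept {labels} (t_crit={diag.t_crit:.2f}), "
              f"R²={model.r_squared:.4f}, prediction at optimum = {preds[m.key]:.3f} {m.unit}")
        model.to_json(OUT / f"model_doe2_{m.key}.json")
    pd.concat(rows).to_csv(OUT / "coefficients_doe2.csv", index=False)
    json.dump({k: round(v, 4) for k, v in preds.items()},
              open(OUT / "predictions_doe2_optimum.json", "w"), indent=1)


if __name__ == "__main__":
    main()
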