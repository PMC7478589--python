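"""Fit the divergence models to the simulated jSFS and select among them.

Compares strict isolation, isolation-with-migration, ancient migration and
secondary contact (the latter with heterogeneous migration and linked
selection, SC2N2M) on the spectrum from 04 by AIC, mirroring the two-stage
protocol: constant-size fits first, then exponential growth added to the
winner.  Writes the model-selection table and best-fit parameters.
"""

import json
import pathlib

from expansionload.demography import (ModelSpec, fit_model, select_model,
                                      values_from_params)
from expansionload.sfs import JointSFS

SEED = 20260925
OUT = pathlib.Path(__file__).resolve().parents[1] / "results" / "demography"
VARIANTS = ("SI", "IM", "AM", "SC", "SC2N", "SC2M", "SC2N2M")


def main():
    obs = JointSFS.from_text(OUT / "observed.sfs")
    fits = {}
    for i, var in enumerate(VARIANTS):
        fits[var] = fit_model(obs, var, n_starts=3, seed=SEED + i,
                              n_genealogies=600, maxiter=500)
        print(f"{var:8s} logL = {fits[var].ll:10.1f}  AIC = {fits[var].aic:10.1f}")
    sel = select_model(fits)
    sel.table.to_csv(OUT / "model_selection.tsv", sep="\t", index=False)
    print(sel.table.to_string(index=False))
    print("ambiguous:", sel.ambiguous)

    best = fits[sel.best]
    growth_spec = ModelSpec.parse(sel.best + "+g")
    init = values_from_params(growth_spec, best.params)
    fit_g = fit_model(obs, growth_spec, n_starts=2, seed=SEED + 99,
                      n_genealogies=600, maxiter=500, init=init)
    print(f"stage 2 ({growth_spec.name}): logL = {fit_g.ll:.1f}, "
          f"AIC = {fit_g.aic:.1f} (stage 1 best AIC {best.aic:.1f})")
    final = fit_g if fit_g.aic < best.aic else best
    payload = {"selected": sel.best, "ambiguous": sel.ambiguous,
               "final_model": final.name,
               "logL": final.ll, "AIC": final.aic, "theta": final.theta,
               "params": values_from_params(final.spec, final.params)}
    (OUT / "best_fit.json").write_text(json.dumps(payload, indent=2))
    print(json.dumps(payload["params"], indent=2))


if __name__ == "__main__":
    main()
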