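"""Globally fit the simulated dispersion profiles to exchange models.

Fits the dT·rG dataset to a 2-state model and the dG·rU dataset to both
2-state and 3-state triangular models (populations and exchange rates shared
across the G and T/U imino nitrogens), compares them by AIC/BIC weights, and
writes the fit parameters as JSON under results/.  The dT·rG profiles are
expected to be explained by a single tautomeric excited state, whereas the
dG·rU profiles should decisively demand the additional anionic state.

Run after 01_simulate_rd.py:  python analysis/02_fit_dispersion.py
"""

import argparse
from pathlib import Path

from wclike.io import read_rd_table, write_results
from wclike.rd_fitting import (
    assign_anion_state,
    fit_three_state_triangular,
    fit_two_state,
    model_selection,
    monte_carlo_uncertainty,
)

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main(seed: int = 1, mc_iter: int = 50) -> None:
    # dT·rG: single tautomeric ES
    data = read_rd_table(RESULTS / "rd_dtrg_ph74.tsv")
    fit2 = fit_two_state(data)
    if mc_iter:
        monte_carlo_uncertainty(data, fit2, n_iter=mc_iter, seed=seed)
    write_results(fit2, RESULTS / "fit_dtrg_2state.json", seed=seed)
    sd = (fit2.param_sd or {})
    print(f"dT·rG 2-state: chi2 {fit2.chi2:.1f}/{fit2.n_obs} points; "
          f"p_ES = {fit2.params['p_es']*100:.4f} ± {sd.get('p_es', 0)*100:.4f} %, "
          f"k_ex = {fit2.params['k_ex']:.0f} ± {sd.get('k_ex', 0):.0f} 1/s")

    # dG·rU: 2-state vs 3-state triangular
    data = read_rd_table(RESULTS / "rd_dgru_ph74.tsv")
    g2 = fit_two_state(data)
    g3 = assign_anion_state(fit_three_state_triangular(data, init_from=g2))
    ranked = model_selection([g2, g3])
    for f, name in ((g2, "fit_dgru_2state.json"), (g3, "fit_dgru_3state.json")):
        write_results(f, RESULTS / name, seed=seed)
    print(f"dG·rU: 2-state chi2 {g2.chi2:.1f} vs 3-state chi2 {g3.chi2:.1f}; "
          f"3-state Akaike weight {g3.akaike_weight:.3f}")
    print(f"  tautomer: p {g3.params['p_es1']*100:.3f} %, "
          f"k_ex {g3.params['k_ex_gs_es1']:.0f} 1/s, "
          f"Δω (G-N1, U-N3) = ({g3.params['dw_ES1_G-N1']:.1f}, "
          f"{g3.params['dw_ES1_U-N3']:.1f}) ppm")
    print(f"  anion:    p {g3.params['p_es2']*100:.3f} %, "
          f"k_ex {g3.params['k_ex_gs_es2']:.0f} 1/s, "
          f"Δω (G-N1, U-N3) = ({g3.params['dw_ES2_G-N1']:.1f}, "
          f"{g3.params['dw_ES2_U-N3']:.1f}) ppm, "
          f"k_ex,minor {g3.params['k_ex_es1_es2']:.0f} 1/s")


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--mc-iter", type=int, default=50)
    args = ap.parse_args()
    main(args.seed, args.mc_iter)
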