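"""Fitting the detergent corona of a membrane-protein dimer to SAXS data.

The full pipeline: a toy transmembrane helix bundle is placed in the
membrane frame, duplicated into a parallel P2 dimer, decorated with a
Monte-Carlo detergent belt anchored on the protein's midplane
circumference, and forward-scattered with the Debye sum.  A planted
1%-noise curve is then refitted from a deliberately wrong starting
geometry.  Takes about a minute.
"""

import numpy as np

from beltsas import (
    ComplexForwardModel,
    FitState,
    RimParams,
    SearchSchedule,
    fit,
    make_toy_protein,
    simulate_complex_curve,
)

protomer = make_toy_protein(n_helices=4, length=26, bundle_radius=8.0)
truth_rim = RimParams(R_xy=28.0, R_z=10.0, D_xy=6.0, D_z=5.0)
q = np.geomspace(0.01, 0.35, 90)

data, truth = simulate_complex_curve(
    protomer, truth_rim, protomer_dx=12.0, q=q, noise=0.01, seed=11,
    box_points=50_000, box_seed=777, coarsen_cell=4.0)
print("planted rim:", truth.params["R_xy"], truth.params["R_z"],
      truth.params["D_xy"], truth.params["D_z"],
      "->", truth.derived["n_dm"], "DM molecules")

model = ComplexForwardModel(protomer, data, box_points=50_000, box_seed=777,
                            q_min=0.02, coarsen_cell=4.0)
start = FitState(rim=RimParams(23.0, 8.5, 5.0, 5.0), protomer_dx=12.0)

# a random search can occasionally stall on the R-D trade-off ridge, so
# run independent restarts and keep the best, stopping once chi^2 is
# at the noise level
result = None
for restart_seed in (1, 2, 3):
    candidate = fit(model, start,
                    SearchSchedule(n_stages=6, decay=0.55,
                                   evals_per_stage=100, seed=restart_seed))
    if result is None or candidate.objective < result.objective:
        result = candidate
    if result.chi2 <= 1.4:
        break

r = result.state.rim
print(f"fitted rim : {r.R_xy:.1f} {r.R_z:.1f} {r.D_xy:.1f} {r.D_z:.1f} "
      f"-> {result.n_dm} DM molecules")
print(f"reduced chi^2 = {result.chi2:.2f}, penalties = {result.penalties}")
print("kept-best objective is non-increasing:",
      bool(np.all(np.diff(result.trace) <= 0)))
# The q < 0.02 1/Å region is excluded from chi^2, mirroring how
# low-q aggregation upturns are handled in real SEC-SAXS data.
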