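"""Generate a synthetic enzyme-substrate trajectory and recover its
precatalytic statistics.

The generator builds a DHA-like chain plus a mock Fe(III)-OH- site per
frame, drawing each candidate hydrogen's distance to the hydroxide oxygen
so that a prescribed fraction of frames is precatalytic (< 4.0 A).  The
analysis then recovers those fractions from coordinates alone.
"""

from loxtraj import synthetic as syn
from loxtraj.reactivity import precatalytic_report

spec = syn.SyntheticSpec(n_frames=150, seed=7, noise_sigma=0.1)
result = syn.make_trajectory(spec)

report, series = precatalytic_report(result.trajectory, result.selection)
print("built-in condition fractions:", spec.precatalytic_fractions)
print("ground-truth realized       :", {
    c: round(result.ground_truth.fraction(f"precat_{c}"), 3) for c in ("H12", "H9", "H15")
})
print("recovered from coordinates  :", {k: round(v, 3) for k, v in report.fractions.items()})
print()
print("closest-H12 distance, first 5 frames (A):",
      [round(float(v), 2) for v in series["dist_H12_OH"].values[:5]])
print("Frames below 4.0 A would be selected as starting points for the")
print("hydrogen-abstraction energy profiles.")
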