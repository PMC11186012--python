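"""Inner-sphere water residence lifetime from a survival curve.

Draws exponential dwell times for the water coordinated to the Gd centre
(one for the aqueous state, one for the membrane-inserted state), builds
the remaining-events curve N(t) and fits N0 exp(-t/tau_m).
"""
import memsolute as ms

for label, tau_true, seed in (("in water", 72.0, 1),
                              ("membrane-inserted", 157.0, 2)):
    dwells = ms.gen_exchange_dwells(tau_true, n_events=500, seed=seed)
    res = ms.survival_tau(dwells)
    print(f"{label:18s} tau_m = {res['tau_m']:6.1f} ns "
          f"(+/- {res['ci']:.1f}), MLE cross-check {res['tau_m_mle']:.1f} ns,"
          f" input {tau_true} ns")
print("Membrane insertion roughly doubles the inner-sphere residence "
      "lifetime; the least-squares and maximum-likelihood estimates agree "
      "for exponential kinetics.")
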