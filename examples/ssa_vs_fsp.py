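"""Cross-check the FSP entry probability against Gillespie simulation.

Uses the scale-0.1 circuit (all concentrations divided by ten) so that
10,000 exact stochastic simulations finish in seconds, and compares the
Monte-Carlo hitting fraction with the certified FSP value.  The two must
agree within the Chernoff half-width plus the FSP error bound.
"""

from fspswitch import (
    chernoff_epsilon,
    estimate_hitting_probability,
    expand_until_certified,
    fsp_error_bound,
    hitting_probability,
    scaled_competence_fixture,
)

fx = scaled_competence_fixture(0.1)
net = fx.network
competence = fx.regions["competence"]
x0 = fx.known["vegetative_state"]
T = 7200.0  # 2 simulated hours

space, sol = expand_until_certified(
    net, fx.recommended_box, {"competence": competence}, x0, T, target_eps=1e-3)
p_fsp = float(hitting_probability(sol, "competence")[-1])
eps_fsp = float(fsp_error_bound(sol)[-1])

est = estimate_hitting_probability(net, x0, competence, T,
                                   n_runs=10_000, delta=0.01, seed=7)

print(f"scaled circuit (omega = 0.1), competence region {competence.name}")
print(f"FSP:  P = {p_fsp:.5f}  (certificate {eps_fsp:.1e})")
print(f"SSA:  p_hat = {est.p_hat:.5f} +- {est.epsilon:.5f} "
      f"({est.n_runs} runs, confidence {1 - est.delta:.0%})")
print(f"difference {abs(est.p_hat - p_fsp):.5f} "
      f"vs allowance {chernoff_epsilon(est.n_runs, est.delta) + eps_fsp:.5f}")
print()
print("The Chernoff bound guarantees the Monte-Carlo fraction deviates from")
print("the true probability by more than epsilon with chance at most delta.")
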