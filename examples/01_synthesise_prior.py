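"""Synthesise a collective prior from five elicited expert summaries.

Each expert's opinion about the log-odds ratio of remission is a normal
summary N(m_k, s_k^2) plus a weight w_k expressing skepticism that the
expert's parameter is commensurate with the new trial's.  The commensurate
predictive step widens each summary; the exp(-w_k^2/s0) rule converts the
w_k into synthesis weights p_k.
"""

from cpssd import (
    CommensuratePriorSpec,
    HistoricalSummary,
    collective_prior,
    hellinger_matrix,
)

experts = [
    HistoricalSummary(-0.26, 0.25, 0.15, "expert1"),
    HistoricalSummary(-0.24, 0.23, 0.20, "expert2"),
    HistoricalSummary(-0.37, 0.22, 0.17, "expert3"),
    HistoricalSummary(-0.34, 0.36, 0.13, "expert4"),
    HistoricalSummary(-0.32, 0.26, 0.20, "expert5"),
]
spec = CommensuratePriorSpec()  # Gamma(2,2) + Gamma(18,3), s0 = 0.05

prior = collective_prior(experts, spec)
print(f"collective prior for the effect: N({prior.mean:.3f}, {prior.variance:.3f})")
print("per-source synthesis (p_k = weight, xi_k^2 = widened variance):")
for src, (p, lam, xi2) in zip(experts, prior.components):
    print(f"  {src.label}: w={src.weight:.2f}  p={p:.2f}  "
          f"N({lam:+.2f}, {src.variance:.2f}) -> xi^2={xi2:.3f}")

# Pairwise Hellinger distances help judge whether the elicited w_k are
# plausible: mutually close summaries justify small w_k.
print("max pairwise Hellinger distance:", f"{hellinger_matrix(experts).max():.3f}")
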