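"""Exact 2x2 inference from carrier counts.

Given carrier counts in a case-control design, compute the two-sided Fisher
exact p value, the sample odds ratio with its zero-cell conventions, and the
exact conditional confidence interval obtained by inverting the noncentral
hypergeometric tail tests.
"""

from rareburden.exact import chisq_yates_p, exact_ci, fisher_two_sided_p, sample_odds_ratio
from rareburden.types import ContingencyTable2x2

N_CASE, N_CONTROL = 1043, 944

examples = {
    "pooled LoF carriers (26 vs 13)": (26, 13),
    "GWAS-proposed LoF subset (17 vs 4)": (17, 4),
    "zero control cell (3 vs 0)": (3, 0),
}

for label, (a, c) in examples.items():
    t = ContingencyTable2x2(a, N_CASE - a, c, N_CONTROL - c)
    p = fisher_two_sided_p(t)
    est = sample_odds_ratio(t)
    ci = exact_ci(t)
    print(f"{label}: Fisher p = {p:.3f}, OR = {est.render()}, 95% CI = {ci.render()}")

t = ContingencyTable2x2(406, N_CASE - 406, 353, N_CONTROL - 353)
print(
    f"total missense carriers (406 vs 353): Yates chi-square p = "
    f"{chisq_yates_p(t):.3f}, OR = {sample_odds_ratio(t).render()}"
)

# A p above 0.05 means the carrier excess in cases is compatible with
# chance; an infinite CI bound reflects an empty cell, not infinite effect.
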