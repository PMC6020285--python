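"""Bench-validation arithmetic: 2^-ddCt folds and compartment percentages.

Relative quantification for one gene from raw Ct values (target vs a
housekeeping reference, treated vs control), Holm-Sidak correction across
a panel of genes, and the mesenchyme/ectoderm percent-expression split.
"""

from crossde import compartment_percent, ddct_fold, holm_sidak
from crossde.qpcr import CONTROL, TREATED, QpcrSample

# treated samples reach threshold one cycle earlier -> twice the template
samples = [
    QpcrSample("t1", TREATED, ct_target=19.0, ct_reference=15.0),
    QpcrSample("t2", TREATED, ct_target=19.1, ct_reference=15.1),
    QpcrSample("t3", TREATED, ct_target=18.9, ct_reference=15.0),
    QpcrSample("c1", CONTROL, ct_target=20.0, ct_reference=15.0),
    QpcrSample("c2", CONTROL, ct_target=20.1, ct_reference=15.1),
    QpcrSample("c3", CONTROL, ct_target=19.9, ct_reference=15.0),
]
res = ddct_fold(samples)
print(f"2^-ddCt fold change (treated/control): {res.fold_change:.3f}")
print(f"Welch t-test on relative quantities:   p = {res.p:.2e}")

# correcting a panel of per-gene p-values for multiple testing
panel_p = [res.p, 0.03, 0.20, 0.64]
adjusted, reject = holm_sidak(panel_p, alpha=0.05)
for p, a, r in zip(panel_p, adjusted, reject):
    print(f"  raw p {p:.3g} -> Holm-Sidak {a:.3g} {'*' if r else ''}")

# tissue-compartment localization: share of total expression per compartment
split = compartment_percent(expr_mes=0.3, expr_ect=0.1, gene="Sox10")
print(
    f"{split.gene}: {split.pct_mesenchyme:.0f}% mesenchyme / "
    f"{split.pct_ectoderm:.0f}% ectoderm"
)
# a fold change of ~2 with one Ct cycle difference is the Livak sanity check;
# the compartment percentages always sum to 100 by construction.
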