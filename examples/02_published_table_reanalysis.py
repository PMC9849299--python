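"""Re-derive published fold ratios and p-values from printed summaries.

The raw animal-level data behind the published transporter tables are not
public, but the printed group summaries (mean, SD, n) are sufficient to
recompute the ratio and p-value columns with the summary-statistic form of
the pooled t-test. Agreement with the printed columns validates both the
bundled reference data and the test implementation.
"""

from qtap import fold_ratio, round_sigfig, student_t_summary
from qtap.refdata import MOUSE_MICROVESSELS

print(f"{'protein':8s} {'ratio':>6s} {'printed':>8s} {'p':>8s} {'printed p':>10s}")
for name in ("ASCT1", "LAT1", "4F2hc", "Abcb1", "GLUT1"):
    row = MOUSE_MICROVESSELS[name]
    ratio = round_sigfig(fold_ratio(row.disease.mean, row.control.mean), 2)
    test = student_t_summary(row.control.mean, row.control.sd, row.control.n,
                             row.disease.mean, row.disease.sd, row.disease.n)
    print(f"{name:8s} {ratio:6g} {row.printed_ratio:8g} "
          f"{test.p_value:8.3f} {row.printed_p:>10s}")
# Each recomputed ratio matches the printed column at 2 significant figures,
# and each recomputed p-value rounds to the printed one — e.g. the amino-acid
# transporter ASCT1 is 2.1-fold up (p ≈ 0.009, printed 0.01) and LAT1 is
# down to 0.38 of control (p ≈ 0.008).
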