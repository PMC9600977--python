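"""Synthetic replication of the paired 2D-vs-3D cohort comparison.

Generates a cohort of 18 synthetic subjects (between-subject variation of
the planted lengths plus 0.5 mm landmark placement noise, drawn
independently for the 2D and 3D tracings), analyses every subject with both
pipelines and prints the cohort comparison table: per-index mean ± SD in
each modality, KS normality p-values and the paired Student's t-test.
"""

from enlowcp import (
    analyze_2d,
    analyze_3d,
    cohort_summary,
    discrepancies,
    generate_cohort,
)

skulls = generate_cohort(n=18, seed=1)

reports_2d = [discrepancies(analyze_2d(s.lm2d)[1], subject=s.subject)
              for s in skulls]
reports_3d = [discrepancies(analyze_3d(s.lm3d)[1], subject=s.subject)
              for s in skulls]

table = cohort_summary(reports_2d, reports_3d, unit="cm")
print(f"paired cohort, n = {table.n}, units = {table.unit}\n")
print(table.to_dataframe().to_string(index=False,
                                     float_format=lambda v: f"{v:.3f}"))

print("""
Reading the table: the two modalities measure the same planted skulls, so
each index's 2D and 3D discrepancy means should agree within noise and the
paired t-test p-values should typically stay above 0.05 — the 3D analysis
reproduces the classical film-based counterpart assessment on matched
geometry. At the 5% level any single cohort can still flag one index by
chance (about one such rejection per index per twenty cohorts); the test
suite therefore checks the property over 100 replicate cohorts.""")
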