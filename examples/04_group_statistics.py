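"""Group contrasts and consciousness-score correlations on a small cohort.

Runs the whole pipeline on a reduced cohort (4 patients per group, 60-s
sessions) and prints the omnibus Kruskal-Wallis tests, pairwise
Mann-Whitney contrasts with Bonferroni correction, and Kendall tau-b
correlations of the variability measures with the CRS-R score.
"""

from eegnetvar import analyze_cohort, run_group_statistics, simulate_cohort

cohort = simulate_cohort(n_per_group=4, duration_s=60.0, seed=3)
table, _, excluded = analyze_cohort(cohort)
print(f"analyzed {len(table)} patients ({len(excluded)} excluded by QC)\n")

stats = run_group_statistics(table)

print("omnibus (Kruskal-Wallis):")
for _, r in stats["omnibus"].iterrows():
    print(f"  {r['contrast']:24s} H={r['statistic']:6.2f}  p={r['p_raw']:.3f}")

print("\npairwise CV of path length (Mann-Whitney U, Bonferroni):")
pw = stats["pairwise"]
for _, r in pw[pw.contrast.str.startswith("cv_cpl")].iterrows():
    print(f"  {r['contrast']:28s} U={r['statistic']:5.1f}  "
          f"p_adj={r['p_adjusted']:.3f}")

print("\nKendall correlations with CRS-R:")
for _, r in stats["correlations"].iterrows():
    print(f"  {r['contrast']:24s} tau={r['tau']:+.2f}  p={r['p_raw']:.3f}")

print("\nAt this reduced size only the strongest contrasts reach "
      "significance; the signs of the correlations are the quantity of "
      "interest (negative for path-length and clustering variability).")
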