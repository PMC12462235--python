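"""Lock-and-key covariation: pouch depth (DP) vs penis length (PL) and
acumen length (LA) across a synthetic species cohort, plus the scalar
descriptors used for single species."""

import cuticlemap as cm

# a small comparative sample, as in real stylopid datasets
cohort = cm.make_cohort(cm.MorphometricCohortSpec(n=8, rho=0.9, seed=1))
for x, y in (("DP", "PL"), ("DP", "LA")):
    res = cm.correlate(cohort, x, y)
    print(f"{x} ~ {y}: Pearson r = {res.r:.3f} "
          f"(95% CI {res.ci95[0]:.3f}..{res.ci95[1]:.3f}, n = {res.n}, p = {res.p:.4f})")
print("note: n = 8 species is underpowered; the interval is the honest summary")

rec = cohort[0]
print(f"\nspecies {rec.id}: DP = {rec.DP:.0f} um, CL = {rec.CL:.0f} um, "
      f"PL = {rec.PL:.0f} um")
print(f"  pouch depth: {cm.pouch_depth_percent(rec.DP, rec.CL):.1f}% of cephalothorax length")
print(f"  fit ratio PL/DP: {cm.fit_ratio(rec.PL, rec.DP):.2f}  (1.0 = perfect mechanical fit)")
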