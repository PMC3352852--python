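"""Case-control GLM on a phantom cohort with a known lesion patch.

Patients carry a 10% white-matter intensity reduction inside a 25 mm
geodesic patch.  The vertex-wise GLM (group + nuisance covariates) with
Benjamini-Hochberg FDR control should light up the patch in the WM and GWR
analyses; adding thickness as a per-vertex regressor tests whether the
contrast effect is explained by local thickness (here it is not — the
effect is intensity-driven and survives the control).

Scaled down for a quick run: 642 vertices, 6 subjects per group.
"""

from gwrkit import (
    CohortSpec,
    DesignSpec,
    PhantomSpec,
    SmootherConfig,
    analyze_cohort,
    generate_cohort,
    summarize_clusters,
)

pspec = PhantomSpec(white_radius=50.0, noise_sd=6.0, voxel_size=1.5,
                    subdivision=3, seed=0)
cspec = CohortSpec(n_per_group=6, effect_wm=0.10, patch_radius_mm=25.0, seed=0)
cohort = generate_cohort(pspec, cspec)

designs = {
    "wm_intensity": DesignSpec(outcome="wm_intensity_sm"),
    "gwr": DesignSpec(outcome="gwr_sm"),
    "gwr | thickness": DesignSpec(outcome="gwr_sm",
                                  pervertex_regressors=("thickness_sm",)),
}
results = analyze_cohort(cohort, designs, smoother=SmootherConfig(fwhm=10.0))

print(f"patch: {cohort.patch_mask.sum()} of {cohort.white.n_vertices} vertices\n")
for label, res in results.items():
    rep = summarize_clusters(res.sig_mask, cohort.white, cohort.patch_mask)
    print(f"{label:16s}: {res.n_significant:4d} significant vertices "
          f"(FDR q=0.05, p threshold {res.fdr_threshold:.2g}), "
          f"Dice vs patch {rep.dice:.2f}")
# Expected pattern: the GWR analyses localize the patch and keep their
# extent under per-vertex thickness control (the simulated effect does not
# act through thickness).  The raw WM-intensity analysis finds the patch
# too but can spill far beyond it: it also picks up per-subject scanner
# gain, which the intensity *ratio* cancels by construction — the reason a
# ratio, not a raw intensity, measures tissue contrast.
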