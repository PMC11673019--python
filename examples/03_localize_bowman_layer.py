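"""Localize the Bowman's-layer resonance from a human/porcine cohort.

Human corneas contain Bowman's layer, porcine corneas do not.  A synthetic
cohort of 20 + 20 unit-max-normalised spectra, in which only the 110 Hz
peak differs between species, is scanned two ways: an unsupervised
per-frequency two-cluster accuracy scan (argmax = distinguishing
frequency) and a leave-one-frequency-out SVC ablation (argmin).  Both
should converge on 110 Hz.
"""

from voct import localization, simulate

cohort = simulate.generate_species_cohort(20, 20, seed=42)

curve_v = localization.vbgmm_frequency_scan(cohort, n_repeats=5, seed=0)
rep_v = localization.locate_distinguishing_frequency(curve_v, "vbgmm_scan")

curve_s = localization.svc_leave_one_frequency_out(cohort, n_repeats=5, seed=0)
rep_s = localization.locate_distinguishing_frequency(curve_s, "svc_ablation")

best_v = max(curve_v, key=lambda r: r.mean_accuracy)
worst_s = min(curve_s, key=lambda r: r.mean_accuracy)

print(
    f"mixture scan:  argmax accuracy at {rep_v.distinguishing_frequency:.0f} Hz "
    f"({best_v.mean_accuracy:.3f} +/- {best_v.accuracy_sd:.3f})"
)
print(
    f"SVC ablation:  argmin accuracy at {rep_s.distinguishing_frequency:.0f} Hz "
    f"({worst_s.mean_accuracy:.3f} +/- {worst_s.accuracy_sd:.3f} when excluded)"
)
print(
    "\nBoth procedures agree: the species contrast — hence Bowman's layer —"
    "\nlives at 110 Hz, i.e. within the anterior 110-120 Hz lamellar band."
)
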